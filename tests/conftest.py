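import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def write_traj(tmp_path):
    """Write a minimal 10-column trajectory file; returns the path."""

    def _write(
        rows,
        name="ant.txt",
        header=(
            "inclination index\tcolony index\ttemperature\thumidity\tdate"
            "\tindividual index\tframe rank\ttime in second\tx\ty"
        ),
        meta=("1", "A", "28", "50", "2012-05-29", "7"),
        trailing_tab=False,
    ):
        path = tmp_path / name
        lines = [header]
        for i, (t, x, y) in enumerate(rows):
            line = "\t".join(meta) + f"\t{i}\t{t}\t{x}\t{y}"
            if trailing_tab:
                line += "\t"
            lines.append(line)
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
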