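import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def raven_file(tmp_path):
    """Write a minimal Raven Pro selection table and return its path."""

    def _write(rows, name="session1.txt", annotation_column="Unit Type"):
        header = ["Selection", "View", "Channel", "Begin Time (s)",
                  "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)",
                  annotation_column]
        lines = ["\t".join(header)]
        for r in rows:
            lines.append("\t".join(str(x) for x in r))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
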