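import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from taxodelin import IdentityMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def abc_matrix() -> IdentityMatrix:
    """3-genome overlap case: A close to B and C, but B far from C.

    At a threshold of 63 the neighborhoods are {A,B,C}, {A,B} and
    {A,C}: A sits in three clusters, B and C in two each.
    """
    v = np.array([[100.0, 65.0, 65.0],
                  [65.0, 100.0, 62.0],
                  [65.0, 62.0, 100.0]])
    return IdentityMatrix(["A", "B", "C"], v, metric_label="AAI")


def brute_force_clusters(matrix: IdentityMatrix, t: float,
                         strict: bool = False) -> set[frozenset]:
    """Independent neighborhood clustering: plain loops over pairs."""
    out = set()
    for g in matrix.genome_ids:
        members = {g}
        for h in matrix.genome_ids:
            if h == g:
                continue
            v = matrix.value(g, h)
            if (v > t) if strict else (round(v, 2) >= round(t, 2) - 1e-9):
                members.add(h)
        out.add(frozenset(members))
    return out
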