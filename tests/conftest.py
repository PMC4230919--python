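import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from oophila.io import AlignedSeqSet
from oophila.simulate import (
    DesignRow,
    default_divergence_matrix,
    simulate_references,
    simulate_survey,
)


@pytest.fixture(scope="session")
def default_panel():
    """Reference panel at the study's divergence scale (I-II 1.2%, III-IV 1.6%, cross 3.7%)."""
    return simulate_references(1000, default_divergence_matrix(), seed=1)


@pytest.fixture(scope="session")
def wide_panel():
    """Panel with all between-subclade divergences >= 3% (separable by NJ and classification)."""
    d = np.full((4, 4), 0.037)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.032
    d[2, 3] = d[3, 2] = 0.032
    return simulate_references(1250, d, seed=7)


def one_site_per_subclade_design(n_capsules=2, clones_per_capsule=3, q=0.0):
    hosts = [
        ("A. maculatum", "I"),
        ("A. gracile", "II"),
        ("L. aurora", "III"),
        ("L. sylvatica", "IV"),
    ]
    return [
        DesignRow(h, f"S{i + 1}", n_capsules, clones_per_capsule, q, {lab: 1.0})
        for i, (h, lab) in enumerate(hosts)
    ]


@pytest.fixture()
def small_survey(wide_panel):
    """24 clones, 6 per planted subclade, gap-free."""
    return simulate_survey(
        wide_panel, one_site_per_subclade_design(), error_rate=0.003, seed=11
    )


@pytest.fixture()
def tiny_alignment():
    return AlignedSeqSet(
        ids=["a", "b", "c"],
        rows=["ACGTACGT", "ACGAACGT", "AC-TACGA"],
    )
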