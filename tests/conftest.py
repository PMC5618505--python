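"""Shared fixtures: random profiles and a hand-built PSI-BLAST ascii PSSM."""

import numpy as np
import pytest

from psfmkit import PSFM, onehot_psfm, ProteinSequence
from psfmkit.synthetic import SyntheticConfig, generate

#: Residue order used by PSI-BLAST ascii PSSM files (differs from canonical).
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def random_psfm(rng: np.random.Generator, L: int, alpha: float = 0.7,
                id: str = "rnd") -> PSFM:
    m = rng.dirichlet(np.full(20, alpha), size=L)
    m /= m.sum(axis=1, keepdims=True)
    p = PSFM(id=id, matrix=m, source="synthetic")
    p.sequence = p.pseudo_sequence()
    return p


def make_pssm_text(rows: list[tuple[str, list[int]]]) -> str:
    """Build a PSI-BLAST ``-out_ascii_pssm`` file from (residue, percentages).

    ``percentages`` are 20 integers in PSI-BLAST column order.  Log-odds are
    filled with zeros; the two trailing per-row floats and the footer mimic
    the real dialect.
    """
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSIBLAST_ORDER) + "   "
        + "  ".join(PSIBLAST_ORDER),
    ]
    for i, (residue, percents) in enumerate(rows, start=1):
        assert len(percents) == 20
        logodds = " ".join(f"{0:3d}" for _ in range(20))
        percs = " ".join(f"{p:3d}" for p in percents)
        lines.append(f"{i:5d} {residue}  {logodds}  {percs}  0.36 0.12")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1380     0.3240",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def aca_psfm():
    """One-hot profile of the 3-mer 'ACA' used in worked examples."""
    return onehot_psfm(ProteinSequence("aca", "ACA"))


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 short, strongly separated profiles (fast model/evaluation tests)."""
    return generate(SyntheticConfig(n_pos=6, n_neg=6, length_range=(20, 30),
                                    effect_size=50.0, seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """20 profiles with strong class signal at realistic lengths."""
    return generate(SyntheticConfig(n_pos=10, n_neg=10, length_range=(50, 80),
                                    effect_size=50.0, seed=11))
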