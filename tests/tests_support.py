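"""Shared helpers for the test suite: simple frames and the R_g oracle."""

import numpy as np

from chitinmech import MolecularFrame


def solute_frame(positions, masses=None):
    """A bare all-solute frame from coordinates (unit masses by default)."""
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    return MolecularFrame(
        positions=pos,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        elements=np.array(["C"] * n, dtype=object),
        molecule_ids=np.zeros(n, dtype=int),
        roles=np.array(["solute"] * n, dtype=object),
    )


def random_solute_frame(rng, n=100):
    return solute_frame(rng.normal(scale=5.0, size=(n, 3)), masses=rng.uniform(1.0, 20.0, n))


def pairwise_rg(frame):
    """Independent radius-of-gyration oracle: the pairwise-distance double sum
    sqrt(Σ_i Σ_j m_i m_j |r_i − r_j|² / (2 (Σm)²)), no center of mass used."""
    m = frame.masses
    r = frame.positions
    total = m.sum()
    acc = 0.0
    for i in range(len(m)):
        for j in range(len(m)):
            acc += m[i] * m[j] * np.sum((r[i] - r[j]) ** 2)
    return np.sqrt(acc / (2.0 * total**2))
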