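"""2D autocorrelation (Broto-Moreau, Moran) and Burden-matrix BCUT descriptors.

The Broto-Moreau autocorrelation of topological structure at lag ``d`` sums the
products of atomic weights over all unordered atom pairs whose topological
distance equals ``d``::

    ATS_d = sum_{i<j, dist(i,j)=d} w_i * w_j          (d >= 1)
    ATS_0 = sum_i w_i^2

Variants: ``AATS`` divides by the number of contributing terms (atom count at
lag 0, pair count otherwise); ``ATSC``/``AATSC`` use centered weights
``w_i - mean(w)``; ``MATS`` is the Moran spatial-autocorrelation index,
``AATSC_d / (sum_i (w_i - mean(w))^2 / A)``. Weights come from three schemes:
atomic mass (``m``), van der Waals volume (``v``) and polarizability (``p``);
hydrogens are explicit atoms and participate in the mean, the pairs and the
distance matrix (the convention calibrated against the reference values for
AATSC0v of nitrobenzene and 1,4-dinitrobenzene).

``BCUTw-1h`` is the highest eigenvalue of the Burden connectivity matrix with
atomic masses on the diagonal; see :func:`bcut_w1h` for the exact convention.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .graph import MoleculeGraph, atom_weights

MAX_LAG = 7

#: the eight descriptors appearing in the adsorption-energy models
MODEL_DESCRIPTORS = (
    "ATSC1m",
    "AATSC0v",
    "MATS1m",
    "BCUTw-1h",
    "AATS1m",
    "AATS7p",
    "ATSC0p",
    "AATSC1p",
)

_NAME_RE = re.compile(r"^(AATSC|ATSC|AATS|ATS|MATS)(\d+)([mvp])$")


class ZeroPairLagWarning(UserWarning):
    """No atom pair exists at the requested lag; the descriptor is set to 0."""


class UnknownDescriptorError(ValueError):
    pass


def _pair_count(g: MoleculeGraph, lag: int) -> int:
    if lag == 0:
        return g.n_atoms
    return int((g.dist == lag).sum() // 2)


def _pair_sum(g: MoleculeGraph, w: np.ndarray, lag: int) -> float:
    if lag == 0:
        return float(np.dot(w, w))
    mask = g.dist == lag
    # each unordered pair appears twice in the symmetric mask
    return float((np.outer(w, w)[mask]).sum() / 2.0)


def ats(g: MoleculeGraph, lag: int, scheme: str) -> float:
    """Broto-Moreau autocorrelation (uncentered). Zero if no pair at ``lag``."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    return _pair_sum(g, atom_weights(g, scheme), lag)


def aats(g: MoleculeGraph, lag: int, scheme: str) -> float:
    """Averaged Broto-Moreau autocorrelation: ``ATS_d`` per contributing term."""
    d = _pair_count(g, lag)
    if d == 0:
        warnings.warn(
            f"no atom pair at lag {lag}; AATS{lag}{scheme} set to 0",
            ZeroPairLagWarning,
            stacklevel=2,
        )
        return 0.0
    return ats(g, lag, scheme) / d


def atsc(g: MoleculeGraph, lag: int, scheme: str) -> float:
    """Centered Broto-Moreau autocorrelation (weights reduced by their mean)."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    w = atom_weights(g, scheme)
    return _pair_sum(g, w - w.mean(), lag)


def aatsc(g: MoleculeGraph, lag: int, scheme: str) -> float:
    """Averaged centered autocorrelation; at lag 0 this is the population
    variance of the weights."""
    d = _pair_count(g, lag)
    if d == 0:
        warnings.warn(
            f"no atom pair at lag {lag}; AATSC{lag}{scheme} set to 0",
            ZeroPairLagWarning,
            stacklevel=2,
        )
        return 0.0
    return atsc(g, lag, scheme) / d


def mats(g: MoleculeGraph, lag: int, scheme: str) -> float:
    """Moran autocorrelation index at lag >= 1.

    ``MATS_d = AATSC_d / (sum_i (w_i - mean(w))^2 / A)``. For homogeneous
    weights the 0/0 form is resolved to 0 by convention (no spatial structure
    in a constant field).
    """
    if lag < 1:
        raise ValueError("Moran autocorrelation requires lag >= 1")
    w = atom_weights(g, scheme)
    denom = float(((w - w.mean()) ** 2).sum()) / g.n_atoms
    if denom == 0.0:
        return 0.0
    d = _pair_count(g, lag)
    if d == 0:
        warnings.warn(
            f"no atom pair at lag {lag}; MATS{lag}{scheme} set to 0",
            ZeroPairLagWarning,
            stacklevel=2,
        )
        return 0.0
    return (atsc(g, lag, scheme) / d) / denom


def burden_matrix(g: MoleculeGraph) -> np.ndarray:
    """Burden connectivity matrix of the hydrogen-suppressed graph.

    Convention (calibrated against the reference BCUTw-1h values 12.15 /
    14.00 / 16.00 for benzene / aniline / nitrobenzene):

    - hydrogens are removed; the matrix is over heavy atoms only;
    - diagonal: exact mass of the most abundant isotope;
    - bonded pairs: ``0.1 / (Kekule bond order)``, i.e. 0.1 single, 0.05
      double, 0.1/3 triple;
    - bonds to a terminal heavy atom (degree 1 in the heavy-atom graph) are
      set to 0.01 instead;
    - non-bonded pairs: 0.001.
    """
    heavy = [k for k, a in enumerate(g.atoms) if a.element != "H"]
    idx = {k: p for p, k in enumerate(heavy)}
    n = len(heavy)
    B = np.full((n, n), 0.001)
    for k in heavy:
        B[idx[k], idx[k]] = g.atoms[k].exact_mass
    hb = [b for b in g.bonds if b.i in idx and b.j in idx]
    degree = np.zeros(n, dtype=int)
    for b in hb:
        degree[idx[b.i]] += 1
        degree[idx[b.j]] += 1
    for b in hb:
        i, j = idx[b.i], idx[b.j]
        v = 0.01 if degree[i] == 1 or degree[j] == 1 else 0.1 / b.order
        B[i, j] = B[j, i] = v
    return B


def bcut_w1h(g: MoleculeGraph) -> float:
    """Highest eigenvalue of the mass-weighted Burden matrix (``BCUTw-1h``)."""
    B = burden_matrix(g)
    if B.shape[0] == 0:
        raise ValueError("no heavy atoms")
    return float(np.linalg.eigvalsh(B).max())


def compute_descriptor(g: MoleculeGraph, name: str) -> float:
    """Compute one named descriptor (e.g. ``"AATSC0v"``, ``"BCUTw-1h"``)."""
    if name == "BCUTw-1h":
        return bcut_w1h(g)
    m = _NAME_RE.match(name)
    if m is None:
        raise UnknownDescriptorError(
            f"unknown descriptor {name!r}; supported: "
            f"(A)ATS(C)<lag><m|v|p> with lag 0..{MAX_LAG}, MATS<lag><m|v|p>, "
            "BCUTw-1h"
        )
    family, lag, scheme = m.group(1), int(m.group(2)), m.group(3)
    if lag > MAX_LAG:
        raise UnknownDescriptorError(f"lag {lag} exceeds maximum {MAX_LAG}")
    fn = {"ATS": ats, "AATS": aats, "ATSC": atsc, "AATSC": aatsc, "MATS": mats}[
        family
    ]
    return fn(g, lag, scheme)


def family_names(schemes=("m", "v", "p"), max_lag: int = MAX_LAG) -> list[str]:
    """All implemented autocorrelation names plus BCUTw-1h, in stable order."""
    out = []
    for fam in ("ATS", "AATS", "ATSC", "AATSC", "MATS"):
        lo = 1 if fam == "MATS" else 0
        for lag in range(lo, max_lag + 1):
            for s in schemes:
                out.append(f"{fam}{lag}{s}")
    out.append("BCUTw-1h")
    return out


def descriptor_table(
    molecules, names=MODEL_DESCRIPTORS, ids=None
) -> pd.DataFrame:
    """Descriptor matrix: one row per molecule, one column per name.

    Deterministic: repeated molecules yield identical rows; column order is
    the order of ``names``.
    """
    names = list(names)
    for n in names:  # validate before any work
        if n != "BCUTw-1h" and _NAME_RE.match(n) is None:
            raise UnknownDescriptorError(
                f"unknown descriptor {n!r}; supported include "
                f"{', '.join(MODEL_DESCRIPTORS)} and the full lag-0..7 families"
            )
    rows = [
        {name: compute_descriptor(g, name) for name in names}
        for g in molecules
    ]
    df = pd.DataFrame(rows, columns=names)
    if ids is not None:
        df.index = pd.Index(ids)
    return df


def drop_constant_descriptors(
    table: pd.DataFrame, drop_zero_variance: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Remove all-zero (optionally zero-variance) columns.

    Mirrors the pre-screening step that discards descriptors carrying no
    information across the compound set. Returns the reduced table and the
    dropped column names.
    """
    if table.shape[0] == 0:
        raise ValueError("empty table")
    dropped = [c for c in table.columns if (table[c] == 0).all()]
    if drop_zero_variance:
        dropped += [
            c
            for c in table.columns
            if c not in dropped and table[c].nunique() == 1
        ]
    return table.drop(columns=dropped), dropped
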