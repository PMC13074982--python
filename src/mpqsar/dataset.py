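"""The packaged adsorption-energy dataset and its bookkeeping.

54 organic compounds (identified by CAS number and name, with curated SMILES)
with DFT-derived aqueous adsorption energies, in kcal/mol, on three
microplastics: polyethylene (PE), polyoxymethylene (POM) and polyvinyl
alcohol (PVA). More negative means stronger binding.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

POLYMERS = ("PE", "POM", "PVA")

# SHA-256 of the canonical numeric payload; guards the fixture against
# accidental edits.
_TABLE1_EXPECTED = (
    "c8f5e45102714ad7a843a69fe993e75e99e0a71cd55a18d56372a9043e12dd3f"
)


class DatasetIntegrityError(RuntimeError):
    pass


@dataclass(frozen=True)
class AdsorptionRecord:
    index: int
    cas: str
    name: str
    smiles: str
    ead_pe: float
    ead_pom: float
    ead_pva: float

    def ead(self, polymer: str) -> float:
        return getattr(self, f"ead_{polymer.lower()}")


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible training/validation partition of compound indices."""

    training_ids: tuple[int, ...]
    validation_ids: tuple[int, ...]
    ratio: tuple[int, int]
    seed: int

    @property
    def n_t(self) -> int:
        return len(self.training_ids)

    @property
    def n_v(self) -> int:
        return len(self.validation_ids)


def _payload(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.6g")
    return buf.getvalue()


def load_dataframe() -> pd.DataFrame:
    text = (resources.files("mpqsar.data") / "table1.csv").read_text()
    # note: '#' appears in SMILES (triple bonds), so pandas' comment
    # handling cannot be used; header comment lines are stripped instead
    body = "\n".join(
        l for l in text.splitlines() if not l.startswith("#")
    )
    df = pd.read_csv(io.StringIO(body))
    digest = hashlib.sha256(_payload(df).encode()).hexdigest()
    if digest != _TABLE1_EXPECTED:
        raise DatasetIntegrityError(
            f"table1.csv checksum mismatch ({digest[:12]}...); "
            "the packaged fixture has been modified"
        )
    if len(df) != 54:
        raise DatasetIntegrityError(f"expected 54 records, found {len(df)}")
    return df


def load_dataset() -> list[AdsorptionRecord]:
    """All 54 records, checksum-verified against the embedded table."""
    df = load_dataframe()
    return [AdsorptionRecord(**row) for row in df.to_dict("records")]


def adsorption_energy(
    e_complex: float, e_mps: float, e_com: float
) -> float:
    """Adsorption energy from total energies of the complex and its parts.

    ``E_ad = E(MP+compound) - E(MP) - E(compound)``; all three inputs must be
    in consistent units, and the result carries those units.
    """
    for v in (e_complex, e_mps, e_com):
        if not np.isfinite(v):
            raise ValueError("energies must be finite")
    return e_complex - e_mps - e_com


def split_dataset(
    records, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> SplitSpec:
    """Random training/validation split at ``ratio`` (default 4:1 -> 43/11).

    The original study's split membership is not published, so splits here are
    seed-parameterized; statistics of split-based models are therefore
    reproducible per seed but comparable to the published ones only in
    distribution.
    """
    if len(ratio) != 2 or ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError(f"invalid ratio {ratio}")
    ids = [r.index for r in records]
    n = len(ids)
    n_v = int(round(n * ratio[1] / (ratio[0] + ratio[1])))
    n_t = n - n_v
    if n_t <= 0 or n_v <= 0:
        raise ValueError(f"ratio {ratio} leaves an empty set for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    return SplitSpec(
        training_ids=tuple(int(i) for i in sorted(perm[:n_t])),
        validation_ids=tuple(int(i) for i in sorted(perm[n_t:])),
        ratio=tuple(ratio),
        seed=seed,
    )
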