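"""Relative potency factor (RPF) cumulation.

When several pesticides share a toxicological endpoint (here, hepatotoxicity),
their residues can be summed after converting each into equivalents of a
chosen index compound.  The potency of compound i relative to the index is

    RPF_i = NOAEL_index / NOAEL_i

so a compound with a lower no-observed-adverse-effect level (more toxic) gets
an RPF above one, and the index compound's RPF is exactly one.  The cumulative
index-equivalent concentration of food category j is then

    C_index,j = sum_i C_i,j * RPF_i

where C_i,j is the residue of compound i in category j (STMR or HR basis).
Compounds absent from a category contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ToxProfile",
    "CategoryResidue",
    "IndexConcentration",
    "compute_rpf",
    "rpf_table",
    "cumulative_index_concentration",
    "cumulate_categories",
]


@dataclass(frozen=True)
class ToxProfile:
    """Toxicological reference data for one compound.

    ``noael`` is in mg/kg body weight per day.  The total uncertainty factor
    is the product of the interspecies and intraspecies factors (default
    10 × 10 = 100).
    """

    compound: str
    noael: float
    is_index: bool = False
    uf_interspecies: float = 10.0
    uf_intraspecies: float = 10.0

    def __post_init__(self) -> None:
        if not self.noael > 0:
            raise ValueError(f"NOAEL must be positive, got {self.noael}")

    @property
    def uf_total(self) -> float:
        return self.uf_interspecies * self.uf_intraspecies


@dataclass(frozen=True)
class CategoryResidue:
    """Residue of one compound in one food category (STMR and HR, mg/kg).

    ``source_crop`` records the crop whose residue was extrapolated to the
    whole category (risk-maximizing convention).  A compound with no data in
    a category simply has no record — a structural zero.
    """

    category: str
    compound: str
    stmr: float
    hr: float
    source_crop: str = ""

    def __post_init__(self) -> None:
        if self.stmr < 0 or self.hr < 0:
            raise ValueError("residues must be non-negative")
        if self.stmr > self.hr + 1e-12:
            raise ValueError(f"STMR {self.stmr} exceeds HR {self.hr}")


@dataclass(frozen=True)
class IndexConcentration:
    """Cumulative index-compound-equivalent concentration of one category."""

    category: str
    c_index: float
    basis: str  # "stmr" or "hr"

    def __post_init__(self) -> None:
        if self.c_index < 0:
            raise ValueError("c_index must be non-negative")
        if self.basis not in ("stmr", "hr"):
            raise ValueError(f"basis must be 'stmr' or 'hr', got {self.basis!r}")


def _index_profile(profiles: Sequence[ToxProfile]) -> ToxProfile:
    idx = [p for p in profiles if p.is_index]
    if len(idx) != 1:
        raise ValueError(f"exactly one index compound required, found {len(idx)}")
    return idx[0]


def compute_rpf(profile: ToxProfile, index_profile: ToxProfile) -> float:
    """RPF of ``profile`` relative to the index compound: NOAEL_index/NOAEL_i."""
    return index_profile.noael / profile.noael


def rpf_table(profiles: Sequence[ToxProfile]) -> dict[str, float]:
    """Map each compound to its RPF; the index compound maps to exactly 1."""
    index = _index_profile(profiles)
    return {p.compound: compute_rpf(p, index) for p in profiles}


def cumulative_index_concentration(
    residues: Sequence[CategoryResidue],
    profiles: Sequence[ToxProfile],
    basis: str = "stmr",
) -> IndexConcentration:
    """Collapse one category's multi-compound residues into index equivalents.

    All residues must share one category; every compound present must have a
    toxicological profile.  An empty residue list cumulates to zero (the
    category label is then "(empty)").
    """
    if basis not in ("stmr", "hr"):
        raise ValueError(f"basis must be 'stmr' or 'hr', got {basis!r}")
    categories = {r.category for r in residues}
    if len(categories) > 1:
        raise ValueError(f"residues span multiple categories: {sorted(categories)}")
    rpfs = rpf_table(profiles)
    total = 0.0
    for r in residues:
        if r.compound not in rpfs:
            raise ValueError(f"no toxicological profile for compound {r.compound!r}")
        total += getattr(r, basis) * rpfs[r.compound]
    category = categories.pop() if categories else "(empty)"
    return IndexConcentration(category=category, c_index=total, basis=basis)


def cumulate_categories(
    residues: Iterable[CategoryResidue],
    profiles: Sequence[ToxProfile],
    basis: str = "stmr",
) -> dict[str, IndexConcentration]:
    """Cumulate every category present in ``residues`` (insertion order kept)."""
    by_cat: dict[str, list[CategoryResidue]] = {}
    for r in residues:
        by_cat.setdefault(r.category, []).append(r)
    return {
        cat: cumulative_index_concentration(rs, profiles, basis)
        for cat, rs in by_cat.items()
    }


def compound_shares(
    residues: Sequence[CategoryResidue],
    profiles: Sequence[ToxProfile],
    basis: str = "stmr",
) -> Mapping[str, float]:
    """Fraction of one category's C_index attributable to each compound.

    Shares are proportional to C_i,j × RPF_i (the only decomposition
    consistent with the linearity of the cumulation); they sum to 1 whenever
    the category's C_index is positive, and are all zero otherwise.
    """
    rpfs = rpf_table(profiles)
    terms = {r.compound: getattr(r, basis) * rpfs[r.compound] for r in residues}
    total = sum(terms.values())
    if total <= 0:
        return {c: 0.0 for c in terms}
    return {c: v / total for c, v in terms.items()}
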