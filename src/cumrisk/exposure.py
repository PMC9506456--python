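"""Two-dimensional Monte Carlo simulation of cumulative dietary exposure.

Chronic exposure of a population group to index-compound equivalents is

    E = sum_j CONS_j * C_index,j / bw        (mg/kg bw/day)

with CONS_j the daily consumption of food category j (g/day, converted to kg
internally), C_index,j the category's cumulative index-equivalent residue
(mg/kg) and bw the body weight (kg).  The risk quotient compares E with the
health-based reference dose NOAEL_index/UF:

    R(%) = 100 * E / (NOAEL_index / UF)

The simulation is nested ("two-dimensional"): the inner loop draws
individual-level variability (body weight, consumption, residue) and yields a
risk distribution whose percentiles (P50/P97.5/P99.9 by default) summarize
population variability; the outer loop repeats the inner loop under
re-sampled input parameters to quantify uncertainty, and the spread of each
percentile across outer replicates gives its confidence band.

Random-number streams are spawned deterministically per (group, outer
replicate) from the master seed and a stable hash of the group id, so results
are independent of group ordering and reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .rpf import ToxProfile, _index_profile

__all__ = [
    "PopulationGroup",
    "ExposureSample",
    "RiskSummary",
    "EngineConfig",
    "ResidueModel",
    "FixedResidue",
    "BootstrapResidue",
    "sample_inner_loop",
    "characterize_risk",
    "run_two_dimensional",
]

_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class PopulationGroup:
    """One region × sex × age stratum of the consumer population.

    ``consumption`` maps food category to (mean g/day, coefficient of
    variation); ``bw_mean``/``bw_cv`` parameterize body weight in kg.
    """

    group_id: str
    region: str
    sex: str
    age_class: str
    bw_mean: float
    bw_cv: float
    consumption: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.bw_mean > 0:
            raise ValueError(f"bw_mean must be positive, got {self.bw_mean}")
        if self.bw_cv < 0:
            raise ValueError("bw_cv must be >= 0")
        for cat, (mean, cv) in self.consumption.items():
            if mean < 0 or cv < 0:
                raise ValueError(f"negative consumption mean/cv for {cat!r}")


@dataclass(frozen=True)
class ExposureSample:
    """One simulated individual's exposure, decomposed two ways.

    Both decompositions (by food category, by compound) sum to ``e_total``.
    """

    group_id: str
    e_total: float
    e_by_category: Mapping[str, float]
    e_by_compound: Mapping[str, float]


@dataclass(frozen=True)
class RiskSummary:
    """Per-group risk percentiles with outer-loop confidence bands.

    ``percentiles`` maps labels like "P97.5" to (point estimate, lower band,
    upper band), all in percent of the reference dose.  The point estimate is
    the median across outer replicates; bands are outer-loop quantiles per
    the configured confidence convention.
    """

    group_id: str
    percentiles: Mapping[str, tuple[float, float, float]]
    n_inner: int
    n_outer: int
    seed: int
    n_redraws: int = 0


@dataclass(frozen=True)
class EngineConfig:
    """Simulation settings.

    ``outer_uncertainty``: "bootstrap" re-samples residue pools and re-draws
    consumption parameters from a pseudo-sample per outer replicate;
    "sampling-only" repeats the inner loop with fresh draws only (Monte Carlo
    noise is then the sole source of band width).
    ``ci`` = "two-sided" uses the 2.5th/97.5th outer-loop percentiles for a
    95% band; "one-sided" uses the 5th/95th.
    """

    n_inner: int = 2000
    n_outer: int = 500
    seed: int = 0
    basis: str = "stmr"
    percentiles: tuple[float, ...] = (50.0, 97.5, 99.9)
    ci: str = "two-sided"
    outer_uncertainty: str = "bootstrap"
    consumption_pseudo_n: int = 100
    bw_family: str = "lognormal"
    consumption_family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.n_inner < 1 or self.n_outer < 1:
            raise ValueError("n_inner and n_outer must be positive")
        if self.ci not in ("two-sided", "one-sided"):
            raise ValueError(f"unknown ci convention {self.ci!r}")
        if self.outer_uncertainty not in ("bootstrap", "sampling-only"):
            raise ValueError(f"unknown outer_uncertainty {self.outer_uncertainty!r}")
        for fam in (self.bw_family, self.consumption_family):
            if fam not in ("lognormal", "normal"):
                raise ValueError(f"unknown distribution family {fam!r}")

    @property
    def band_quantiles(self) -> tuple[float, float]:
        return (2.5, 97.5) if self.ci == "two-sided" else (5.0, 95.0)


# --------------------------------------------------------------------------
# residue concentration models


class ResidueModel:
    """Per-category residue-concentration sampler (mg/kg, index equivalents)."""

    categories: tuple[str, ...]

    def resample(self, rng: np.random.Generator) -> "ResidueModel":
        """Outer-loop uncertainty re-draw; the default is parameter-free."""
        return self

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, n_categories) concentration draws."""
        raise NotImplementedError

    def compound_share_matrix(self, compounds: Sequence[str]) -> np.ndarray:
        """(n_categories, n_compounds) fractional attribution of each
        category's concentration to each compound; rows sum to 1 (or 0 for a
        residue-free category)."""
        raise NotImplementedError


@dataclass(frozen=True)
class FixedResidue(ResidueModel):
    """Deterministic per-category index-equivalent concentrations.

    ``shares`` optionally carries the per-category compound attribution
    (e.g. from :func:`cumrisk.rpf.compound_shares`); without it the whole
    concentration is attributed to a single pseudo-compound "all".
    """

    c_index: Mapping[str, float]
    shares: Mapping[str, Mapping[str, float]] | None = None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.c_index)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        vals = np.array([self.c_index[c] for c in self.categories], dtype=float)
        return np.broadcast_to(vals, (n, vals.size)).copy()

    def compound_share_matrix(self, compounds: Sequence[str]) -> np.ndarray:
        cats = self.categories
        mat = np.zeros((len(cats), len(compounds)))
        for i, cat in enumerate(cats):
            if self.shares is None:
                mat[i, :] = 1.0 / len(compounds)
            else:
                for j, comp in enumerate(compounds):
                    mat[i, j] = self.shares.get(cat, {}).get(comp, 0.0)
        return mat


@dataclass(frozen=True)
class BootstrapResidue(ResidueModel):
    """Empirical-bootstrap residues: each inner draw picks one value from a
    per-category pool of candidate index-equivalent concentrations; the
    outer loop re-samples each pool with replacement."""

    pools: Mapping[str, np.ndarray]
    shares: Mapping[str, Mapping[str, float]] | None = None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.pools)

    def resample(self, rng: np.random.Generator) -> "BootstrapResidue":
        new_pools = {
            cat: np.asarray(pool)[rng.integers(0, len(pool), size=len(pool))]
            for cat, pool in self.pools.items()
        }
        return BootstrapResidue(pools=new_pools, shares=self.shares)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, len(self.pools)))
        for j, cat in enumerate(self.categories):
            pool = np.asarray(self.pools[cat], dtype=float)
            out[:, j] = pool[rng.integers(0, pool.size, size=n)]
        return out

    def compound_share_matrix(self, compounds: Sequence[str]) -> np.ndarray:
        return FixedResidue(
            c_index={c: 0.0 for c in self.categories}, shares=self.shares
        ).compound_share_matrix(compounds)


# --------------------------------------------------------------------------
# sampling primitives


def _positive_draws(
    mean: float, cv: float, n: int, rng: np.random.Generator, family: str
) -> tuple[np.ndarray, int]:
    """Draw n positive values with the given mean and CV.

    Lognormal draws are positive by construction and written as
    mean * exp(sigma Z - sigma^2/2), so with common random numbers the draws
    are monotone in the mean.  Normal draws are truncated at zero by redraw;
    the redraw count is returned.
    """
    if mean == 0 or cv == 0:
        return np.full(n, float(mean)), 0
    if family == "lognormal":
        sigma = np.sqrt(np.log1p(cv * cv))
        z = rng.standard_normal(n)
        return mean * np.exp(sigma * z - 0.5 * sigma * sigma), 0
    # truncated normal via redraw
    vals = mean * (1.0 + cv * rng.standard_normal(n))
    redraws = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = vals <= 0
        nbad = int(bad.sum())
        if nbad == 0:
            break
        redraws += nbad
        vals[bad] = mean * (1.0 + cv * rng.standard_normal(nbad))
    else:
        raise RuntimeError("could not draw positive values; check mean/cv")
    return vals, redraws


def _group_stream(seed: int, group_id: str, outer_index: int) -> np.random.Generator:
    """Independent, order-invariant substream for one (group, outer rep)."""
    digest = hashlib.sha256(group_id.encode()).digest()
    ghash = int.from_bytes(digest[:8], "big") % (2**63)
    return np.random.default_rng(np.random.SeedSequence([seed, ghash, outer_index]))


def _inner_arrays(
    group: PopulationGroup,
    residues: ResidueModel,
    n: int,
    rng: np.random.Generator,
    config: EngineConfig,
    cons_params: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, int]:
    """(n, n_categories) per-category exposures in mg/kg bw/day + redraws."""
    cats = residues.categories
    params = cons_params if cons_params is not None else group.consumption
    bw, redraws = _positive_draws(group.bw_mean, group.bw_cv, n, rng, config.bw_family)
    cons = np.zeros((n, len(cats)))
    for j, cat in enumerate(cats):
        mean, cv = params.get(cat, (0.0, 0.0))
        draws, r = _positive_draws(mean, cv, n, rng, config.consumption_family)
        cons[:, j] = draws
        redraws += r
    conc = residues.draw(n, rng)
    e_cat = (cons / 1000.0) * conc / bw[:, None]  # g/day → kg/day
    return e_cat, redraws


def sample_inner_loop(
    group: PopulationGroup,
    residues: ResidueModel | Mapping[str, float],
    n_inner: int,
    rng: np.random.Generator,
    config: EngineConfig | None = None,
    compounds: Sequence[str] = ("all",),
) -> list[ExposureSample]:
    """Run one inner (variability) loop and return individual exposures.

    ``residues`` may be a plain mapping of category → fixed index-equivalent
    concentration, or any :class:`ResidueModel`.  Deterministic given the
    generator state.
    """
    if n_inner < 1:
        raise ValueError("n_inner must be >= 1")
    if isinstance(residues, Mapping):
        residues = FixedResidue(c_index=dict(residues))
    config = config or EngineConfig()
    e_cat, _ = _inner_arrays(group, residues, n_inner, rng, config)
    if not np.all(np.isfinite(e_cat)):
        raise FloatingPointError("non-finite exposure sample encountered")
    share = residues.compound_share_matrix(compounds)  # (ncat, ncomp)
    e_comp = e_cat @ share
    cats = residues.categories
    return [
        ExposureSample(
            group_id=group.group_id,
            e_total=float(e_cat[i].sum()),
            e_by_category={c: float(e_cat[i, j]) for j, c in enumerate(cats)},
            e_by_compound={c: float(e_comp[i, j]) for j, c in enumerate(compounds)},
        )
        for i in range(n_inner)
    ]


def characterize_risk(
    exposure: ExposureSample | float, tox: Sequence[ToxProfile]
) -> float:
    """Risk quotient in percent: 100 · E / (NOAEL_index / UF_total)."""
    index = _index_profile(tox)
    e_total = exposure.e_total if isinstance(exposure, ExposureSample) else float(exposure)
    return 100.0 * e_total / (index.noael / index.uf_total)


def _bootstrap_consumption(
    group: PopulationGroup, rng: np.random.Generator, config: EngineConfig
) -> Mapping[str, tuple[float, float]]:
    """Re-draw per-category consumption parameters from a pseudo-sample.

    Emulates parameter uncertainty from a finite survey: draw m records from
    the variability distribution, re-fit mean and CV from them.
    """
    m = config.consumption_pseudo_n
    out: dict[str, tuple[float, float]] = {}
    for cat, (mean, cv) in group.consumption.items():
        if mean == 0 or cv == 0:
            out[cat] = (mean, cv)
            continue
        draws, _ = _positive_draws(mean, cv, m, rng, config.consumption_family)
        smean = float(draws.mean())
        scv = float(draws.std(ddof=1) / smean) if smean > 0 else 0.0
        out[cat] = (smean, scv)
    return out


def run_two_dimensional(
    groups: Sequence[PopulationGroup],
    residues: ResidueModel | Mapping[str, float],
    tox: Sequence[ToxProfile],
    config: EngineConfig | None = None,
) -> list[RiskSummary]:
    """Full nested simulation: one RiskSummary per population group.

    For every outer replicate the input parameters are re-drawn per the
    configured uncertainty model, one inner loop runs, and the configured
    risk percentiles are recorded; the point estimate of each percentile is
    its median across outer replicates and the confidence band its outer
    2.5th/97.5th (or 5th/95th) percentiles.  Bit-reproducible from
    ``config.seed`` regardless of group order.
    """
    config = config or EngineConfig()
    if isinstance(residues, Mapping):
        residues = FixedResidue(c_index=dict(residues))
    index = _index_profile(tox)
    ref_dose = index.noael / index.uf_total  # mg/kg bw/day
    lo_q, hi_q = config.band_quantiles

    summaries: list[RiskSummary] = []
    for group in groups:
        stats = np.empty((config.n_outer, len(config.percentiles)))
        redraws_total = 0
        for rep in range(config.n_outer):
            rng = _group_stream(config.seed, group.group_id, rep)
            if config.outer_uncertainty == "bootstrap":
                model = residues.resample(rng)
                cons_params = _bootstrap_consumption(group, rng, config)
            else:
                model, cons_params = residues, None
            e_cat, redraws = _inner_arrays(
                group, model, config.n_inner, rng, config, cons_params
            )
            redraws_total += redraws
            risks = 100.0 * e_cat.sum(axis=1) / ref_dose
            if not np.all(np.isfinite(risks)):
                raise FloatingPointError(
                    f"non-finite risk samples for group {group.group_id!r}"
                )
            stats[rep] = np.percentile(risks, config.percentiles)
        perc_map = {
            f"P{p:g}": (
                float(np.median(stats[:, i])),
                float(np.percentile(stats[:, i], lo_q)),
                float(np.percentile(stats[:, i], hi_q)),
            )
            for i, p in enumerate(config.percentiles)
        }
        summaries.append(
            RiskSummary(
                group_id=group.group_id,
                percentiles=perc_map,
                n_inner=config.n_inner,
                n_outer=config.n_outer,
                seed=config.seed,
                n_redraws=redraws_total,
            )
        )
    return summaries
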