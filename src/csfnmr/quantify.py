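"""Metabolite quantification by summed bucket integrals, control
normalisation, and one-way ANOVA with Dunnett many-to-one comparisons.

A metabolite is defined by the chemical-shift regions its resonances occupy
(each region an exact union of 0.02-ppm buckets).  Its abundance in a sample
is the sum of the bucket integrals whose intervals lie wholly inside any of
those regions; abundances are reported relative to the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import BucketTable

__all__ = [
    "MetaboliteDefinition",
    "AbundanceTable",
    "DefinitionError",
    "DegenerateControlError",
    "InsufficientGroupError",
    "DEFAULT_METABOLITES",
    "summed_integral",
    "abundance_table",
    "normalize_to_control",
    "group_comparison",
    "significance_stars",
]

_EPS = 1e-9


class DefinitionError(ValueError):
    pass


class DegenerateControlError(ValueError):
    pass


class InsufficientGroupError(ValueError):
    pass


@dataclass(frozen=True)
class MetaboliteDefinition:
    """A named metabolite and the ppm regions summed for its abundance."""

    name: str
    regions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        regs = tuple((float(lo), float(hi)) for lo, hi in self.regions)
        object.__setattr__(self, "regions", regs)
        for lo, hi in regs:
            if not lo < hi:
                raise DefinitionError(f"{self.name}: region [{lo}, {hi}] needs low < high")
            if lo < 0.2 - _EPS or hi > 9.6 + _EPS:
                raise DefinitionError(f"{self.name}: region [{lo}, {hi}] outside [0.2, 9.6]")
        ordered = sorted(regs)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
            if b_lo < a_hi - _EPS:
                raise DefinitionError(f"{self.name}: regions overlap near {b_lo}")

    def contains_bucket(self, midpoint: float, width: float) -> bool:
        """True when the full bucket interval lies within one of the regions."""
        lo, hi = midpoint - width / 2.0, midpoint + width / 2.0
        return any(lo >= r_lo - _EPS and hi <= r_hi + _EPS for r_lo, r_hi in self.regions)


#: Discriminating CSF metabolites and their resonance regions.
DEFAULT_METABOLITES: tuple[MetaboliteDefinition, ...] = (
    MetaboliteDefinition("Lactic acid", ((1.32, 1.34), (4.10, 4.14))),
    MetaboliteDefinition("Citric acid", ((2.64, 2.66),)),
    MetaboliteDefinition(
        "Glucose",
        (
            (3.24, 3.28),
            (3.38, 3.44),
            (3.46, 3.52),
            (3.54, 3.56),
            (3.70, 3.80),
            (3.82, 3.86),
            (3.88, 3.92),
        ),
    ),
    MetaboliteDefinition("Ethanol", ((1.18, 1.20), (3.66, 3.68))),
)


@dataclass
class AbundanceTable:
    """Samples x metabolites matrix of summed integrals."""

    sample_ids: list[str]
    metabolite_names: list[str]
    values: np.ndarray
    normalized: bool = False
    control_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.metabolite_names)):
            raise ValueError("values shape does not match sample/metabolite labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.metabolite_names,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.metabolite_names.index(name)]


def summed_integral(buckets: BucketTable, metabolite: MetaboliteDefinition) -> np.ndarray:
    """Per-sample abundance: sum of bucket integrals inside the regions.

    A bucket contributes iff its full interval lies within a region (closed
    containment); every region must capture at least one retained bucket.
    """
    width = buckets.width
    member = np.zeros(buckets.n_buckets, dtype=bool)
    for r_lo, r_hi in metabolite.regions:
        lo = buckets.bucket_midpoints - width / 2.0
        hi = buckets.bucket_midpoints + width / 2.0
        in_region = (lo >= r_lo - _EPS) & (hi <= r_hi + _EPS)
        if not in_region.any():
            raise DefinitionError(
                f"{metabolite.name}: region [{r_lo}, {r_hi}] matches no retained bucket"
            )
        member |= in_region
    return buckets.values[:, member].sum(axis=1)


def abundance_table(
    buckets: BucketTable,
    metabolites: Sequence[MetaboliteDefinition] = DEFAULT_METABOLITES,
) -> AbundanceTable:
    values = np.column_stack([summed_integral(buckets, m) for m in metabolites])
    return AbundanceTable(list(buckets.sample_ids), [m.name for m in metabolites], values)


def normalize_to_control(abundances: AbundanceTable, control_ids: Sequence[str]) -> AbundanceTable:
    """Divide every metabolite by its control-group mean (which becomes 1)."""
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise InsufficientGroupError("need at least 2 control samples to normalise")
    index = {s: i for i, s in enumerate(abundances.sample_ids)}
    rows = [index[s] for s in control_ids]
    means = abundances.values[rows].mean(axis=0)
    if np.any(np.abs(means) <= _EPS):
        bad = abundances.metabolite_names[int(np.argmin(np.abs(means)))]
        raise DegenerateControlError(f"control mean of {bad!r} is zero")
    return AbundanceTable(
        list(abundances.sample_ids),
        list(abundances.metabolite_names),
        abundances.values / means,
        normalized=True,
        control_means=means,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_comparison(
    abundances: AbundanceTable,
    groups: Mapping[str, Sequence[str]],
    reference: str = "control",
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one comparison against control.

    ``groups`` maps a group label to its sample ids (groups may overlap, as
    with nested follow-up cohorts).  Per metabolite: a fixed-effects ANOVA
    across all groups, then two-sided Dunnett comparisons of every non-
    reference group against the reference at familywise alpha 0.05.  Returns
    a tidy frame with one row per (metabolite, comparison group).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing from groups")
    if len(groups) < 2:
        raise InsufficientGroupError("need at least 2 groups")
    for label, ids in groups.items():
        if len(ids) < 2:
            raise InsufficientGroupError(f"group {label!r} has fewer than 2 samples")
    index = {s: i for i, s in enumerate(abundances.sample_ids)}
    rows_by_group = {g: [index[s] for s in ids] for g, ids in groups.items()}
    case_labels = [g for g in groups if g != reference]

    records = []
    for j, name in enumerate(abundances.metabolite_names):
        col = abundances.values[:, j]
        arrays = {g: col[r] for g, r in rows_by_group.items()}
        f_stat, anova_p = stats.f_oneway(*arrays.values())
        # fixed rng: the multivariate-t integration is randomised quadrature
        dunnett = stats.dunnett(
            *[arrays[g] for g in case_labels],
            control=arrays[reference],
            alternative="two-sided",
            rng=np.random.default_rng(0),
        )
        for g, p_adj in zip(case_labels, dunnett.pvalue):
            records.append(
                {
                    "metabolite": name,
                    "group": g,
                    "n": len(arrays[g]),
                    "mean": float(arrays[g].mean()),
                    "sd": float(arrays[g].std(ddof=1)),
                    "anova_F": float(f_stat),
                    "anova_p": float(anova_p),
                    "dunnett_p": float(p_adj),
                    "stars": significance_stars(float(p_adj)),
                }
            )
    return pd.DataFrame.from_records(records)
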