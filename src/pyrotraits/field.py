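"""Projection of the lab trait catalogue onto field communities.

Lab and field ASVs are merged by exact sequence identity.  Per field sample
the module computes total relative abundance of each trait group (and an
"any trait" aggregate that counts multi-trait taxa once), copy-number
normalized abundances, community-weighted mean predicted 16S rRNA gene copy
number, qPCR-scaled absolute abundances, and mean Bray-Curtis dissimilarity
to the matched unburned samples of the same vegetation x horizon x year
stratum.  Trait abundance is then regressed on the burn severity index with
a years-post-fire interaction that is dropped when not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import braycurtis

from pyrotraits.io import (
    CountTable,
    SampleRecord,
    TaxonRecord,
    Timepoint,
    ValidationError,
    relative_abundance,
)
from pyrotraits.traits import TraitCatalogue

__all__ = [
    "TraitAbundanceRecord",
    "SeverityModelFit",
    "match_taxa",
    "trait_total_abundance",
    "copy_number_normalize",
    "weighted_mean_copy_number",
    "absolute_abundance",
    "bray_curtis_to_unburned",
    "severity_regression",
]

ANY_TRAIT = "any_trait"


@dataclass
class TraitAbundanceRecord:
    sample_id: str
    trait: str
    total_relative_abundance: float
    normalized_relative_abundance: float
    absolute_abundance: float | None
    years_post_fire: int | None
    burn_severity_index: float | None


@dataclass
class SeverityModelFit:
    """OLS of trait abundance ~ severity * year, interaction dropped when
    its p-value is >= the drop threshold."""

    trait: str
    intercept_by_year: dict[int, float]
    slope_by_year: dict[int, float]
    interaction_p: float
    interaction_dropped: bool
    r2_adjusted: float
    overall_p: float


def match_taxa(
    lab_taxa: Sequence[TaxonRecord], field_taxa: Sequence[TaxonRecord]
) -> dict[str, str]:
    """Map lab taxon_id -> field taxon_id by exact sequence identity."""
    for name, taxa in (("lab", lab_taxa), ("field", field_taxa)):
        seen: dict[str, str] = {}
        dupes: list[tuple[str, str]] = []
        for t in taxa:
            if t.sequence in seen:
                dupes.append((seen[t.sequence], t.taxon_id))
            else:
                seen[t.sequence] = t.taxon_id
        if dupes:
            raise ValidationError(f"duplicate sequences within {name} dataset: {dupes}")
    field_by_seq = {t.sequence: t.taxon_id for t in field_taxa}
    return {
        t.taxon_id: field_by_seq[t.sequence]
        for t in lab_taxa
        if t.sequence in field_by_seq
    }


def copy_number_normalize(
    field: CountTable, taxa: Sequence[TaxonRecord]
) -> np.ndarray:
    """Relative abundances after dividing counts by each taxon's predicted
    16S rRNA gene copy number and renormalizing columns to 1.

    Taxa without a copy-number prediction default to 1.
    """
    by_id = {t.taxon_id: t.predicted_copy_number for t in taxa}
    copies = np.array([by_id.get(tid, 1.0) for tid in field.taxon_ids])
    if np.any(copies <= 0):
        raise ValidationError("predicted copy numbers must be positive")
    adj = field.counts / copies[:, None]
    return adj / adj.sum(axis=0, keepdims=True)


def weighted_mean_copy_number(
    relabund: np.ndarray, taxa: Sequence[TaxonRecord]
) -> float:
    """Community-weighted mean predicted rRNA gene copy number:
    sum of relative abundance x predicted copy number."""
    copies = np.array([t.predicted_copy_number for t in taxa])
    r = np.asarray(relabund, dtype=float)
    if abs(r.sum() - 1.0) > 1e-6:
        raise ValidationError("relative abundances must sum to 1")
    return float(r @ copies)


def absolute_abundance(trait_relabund: float, qpcr_total: float | None) -> float | None:
    """16S copies per g: relative abundance x qPCR total; missing qPCR
    propagates as missing."""
    if qpcr_total is None:
        return None
    return trait_relabund * qpcr_total


def trait_total_abundance(
    field: CountTable,
    catalogue: TraitCatalogue,
    match: Mapping[str, str],
    taxa: Sequence[TaxonRecord],
    samples: Sequence[SampleRecord],
) -> list[TraitAbundanceRecord]:
    """Per sample and trait, total (and copy-number-normalized, and
    absolute) relative abundance of matched trait taxa.

    Multi-trait taxa count toward each of their traits; the "any_trait"
    aggregate counts each taxon once.
    """
    samples_by_id = {s.sample_id: s for s in samples}
    rel = relative_abundance(field)
    norm = copy_number_normalize(field, taxa)
    row_of = {tid: i for i, tid in enumerate(field.taxon_ids)}

    trait_rows: dict[str, list[int]] = {t: [] for t in ("survivor", "fast_grower", "postfire_affinity")}
    any_rows: set[int] = set()
    for lab_id, traits in catalogue.entries.items():
        fid = match.get(lab_id)
        if fid is None or fid not in row_of:
            continue
        i = row_of[fid]
        any_rows.add(i)
        for trait in traits:
            trait_rows.setdefault(trait, []).append(i)

    records: list[TraitAbundanceRecord] = []
    groups = {**{t: sorted(set(r)) for t, r in trait_rows.items()}, ANY_TRAIT: sorted(any_rows)}
    for j, sid in enumerate(field.sample_ids):
        meta = samples_by_id.get(sid)
        for trait, rows in groups.items():
            tot = float(rel[rows, j].sum()) if rows else 0.0
            ntot = float(norm[rows, j].sum()) if rows else 0.0
            qpcr = meta.qpcr_total_copies_per_g if meta else None
            records.append(
                TraitAbundanceRecord(
                    sample_id=sid,
                    trait=trait,
                    total_relative_abundance=tot,
                    normalized_relative_abundance=ntot,
                    absolute_abundance=absolute_abundance(tot, qpcr),
                    years_post_fire=meta.years_post_fire if meta else None,
                    burn_severity_index=meta.burn_severity_index if meta else None,
                )
            )
    return records


def records_to_frame(records: Sequence[TraitAbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def bray_curtis_to_unburned(
    field: CountTable, samples: Sequence[SampleRecord]
) -> dict[str, float]:
    """Per burned field sample, mean Bray-Curtis dissimilarity (on relative
    abundances) to all unburned samples matched by vegetation, horizon and
    year."""
    samples_by_id = {s.sample_id: s for s in samples}
    rel = relative_abundance(field)
    col_of = {sid: j for j, sid in enumerate(field.sample_ids)}

    def stratum(s: SampleRecord):
        return (s.vegetation, s.horizon, s.years_post_fire)

    unburned: dict[tuple, list[str]] = {}
    for s in samples:
        if s.sample_id in col_of and s.timepoint is Timepoint.FIELD and not s.burned:
            unburned.setdefault(stratum(s), []).append(s.sample_id)

    out: dict[str, float] = {}
    missing: set[tuple] = set()
    for sid in field.sample_ids:
        s = samples_by_id.get(sid)
        if s is None or s.timepoint is not Timepoint.FIELD or not s.burned:
            continue
        mates = unburned.get(stratum(s), [])
        if not mates:
            missing.add(stratum(s))
            continue
        x = rel[:, col_of[sid]]
        out[sid] = float(
            np.mean([braycurtis(x, rel[:, col_of[m]]) for m in mates])
        )
    if missing:
        raise ValidationError(f"no matched unburned samples for strata: {sorted(missing)}")
    return out


def severity_regression(
    records: Sequence[TraitAbundanceRecord],
    trait: str,
    interaction_alpha: float = 0.05,
) -> SeverityModelFit:
    """OLS of trait abundance on severity, year (categorical) and their
    interaction; the interaction is dropped when p >= ``interaction_alpha``
    and the additive model is reported instead."""
    rows = [
        r
        for r in records
        if r.trait == trait
        and r.burn_severity_index is not None
        and r.years_post_fire is not None
    ]
    years = sorted({r.years_post_fire for r in rows})
    if len(years) != 2:
        raise ValidationError("both year groups must be represented")
    if len(rows) < 8:
        raise ValidationError("need at least 8 samples for the severity regression")
    y0, y1 = years
    yvals = np.array([r.total_relative_abundance for r in rows])
    sev = np.array([r.burn_severity_index for r in rows])
    is_late = np.array([1.0 if r.years_post_fire == y1 else 0.0 for r in rows])

    X_full = np.column_stack([np.ones(len(rows)), sev, is_late, sev * is_late])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValidationError("severity design is rank deficient (collinear terms)")
    with np.errstate(divide="ignore", invalid="ignore"):
        full = sm.OLS(yvals, X_full).fit()
        p_int = float(full.pvalues[3])
        dropped = np.isfinite(p_int) and p_int >= interaction_alpha
        if dropped:
            model = sm.OLS(yvals, X_full[:, :3]).fit()
            slope = {y0: float(model.params[1]), y1: float(model.params[1])}
            intercept = {
                y0: float(model.params[0]),
                y1: float(model.params[0] + model.params[2]),
            }
        else:
            model = full
            slope = {
                y0: float(model.params[1]),
                y1: float(model.params[1] + model.params[3]),
            }
            intercept = {
                y0: float(model.params[0]),
                y1: float(model.params[0] + model.params[2]),
            }
        overall_p = float(model.f_pvalue)
        r2 = float(model.rsquared_adj)
    return SeverityModelFit(
        trait=trait,
        intercept_by_year=intercept,
        slope_by_year=slope,
        interaction_p=p_int,
        interaction_dropped=bool(dropped),
        r2_adjusted=r2,
        overall_p=overall_p,
    )
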