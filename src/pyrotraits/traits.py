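"""Trait calling: orchestrates the three trait-defining contrasts.

Traits are assigned from three beta-binomial contrasts on the lab data, run
separately for organic and mineral horizons with a centred pH covariate:

* ``survivor`` — enriched in burned vs unburned soil 24 h post-burn, and
  viable by the RNA:DNA ratio filter (ratio >= 1 over burned retained
  cores);
* ``fast_grower`` — enriched in burned soil at 5 weeks vs 24 h post-burn
  (burned cores only);
* ``postfire_affinity`` — enriched in burned vs unburned soil after
  inoculation and a 6-month incubation.

Only cores that demonstrably experienced fire (maximum thermocouple
temperature strictly above 50 degC) and their site controls enter any
contrast.  Significant calls (BH q < 0.05, log2 fold change > 0) then pass
an effect-size filter that removes taxa whose log2 fold change falls more
than one standard deviation below the mean of the significant positive
responders of that experiment x horizon.  The union over horizons forms the
trait catalogue; traits are non-exclusive sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pyrotraits.diffabund import ContrastDesign, DiffAbundResult, fit_taxa
from pyrotraits.io import (
    CountTable,
    Horizon,
    SampleRecord,
    TaxonRecord,
    Timepoint,
    ValidationError,
    relative_abundance,
    write_taxa_fasta,
)

__all__ = [
    "TraitCall",
    "TraitCatalogue",
    "select_burn_exposed",
    "viability_filter",
    "effect_size_filter",
    "call_trait",
    "build_catalogue",
]

CONTRASTS = ("survivor", "fast_grower", "postfire_affinity")


@dataclass
class TraitCall:
    """One (taxon, trait) call with its provenance."""

    taxon_id: str
    trait: str
    horizon: str
    log2fc: float
    q_value: float


@dataclass
class TraitCatalogue:
    """Map taxon -> assigned trait set, with per-call provenance."""

    entries: dict[str, set[str]] = dc_field(default_factory=dict)
    provenance: list[TraitCall] = dc_field(default_factory=list)

    def taxa_with(self, trait: str) -> set[str]:
        return {t for t, ts in self.entries.items() if trait in ts}

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_id": c.taxon_id,
                "trait": c.trait,
                "horizon": c.horizon,
                "log2fc": c.log2fc,
                "q_value": c.q_value,
            }
            for c in self.provenance
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "trait", "horizon", "log2fc", "q_value"])

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["traits"] = df["taxon_id"].map(lambda t: ";".join(sorted(self.entries[t])))
        df.to_csv(path, index=False)

    def write_fasta(self, taxa: Sequence[TaxonRecord], path: str | Path) -> None:
        by_id = {t.taxon_id: t for t in taxa}
        write_taxa_fasta([by_id[t] for t in sorted(self.entries) if t in by_id], path)


def select_burn_exposed(samples: Sequence[SampleRecord], temp_threshold_C: float = 50.0) -> set[str]:
    """Retain burned cores with max temperature strictly above the threshold,
    plus the matching unburned control of each retained burned core.

    Matching is by site, horizon and timepoint.  A burned lab core without a
    recorded temperature is an error.
    """
    retained: set[str] = set()
    controls = {
        (s.site_id, s.horizon, s.timepoint): s.sample_id
        for s in samples
        if not s.burned and s.timepoint is not Timepoint.FIELD
    }
    for s in samples:
        if s.timepoint is Timepoint.FIELD or not s.burned:
            continue
        if s.max_temp_C is None:
            raise ValidationError(f"burned core {s.sample_id} has no recorded temperature")
        if s.max_temp_C > temp_threshold_C:
            retained.add(s.sample_id)
            ctrl = controls.get((s.site_id, s.horizon, s.timepoint))
            if ctrl is not None:
                retained.add(ctrl)
    return retained


def viability_filter(
    dna: CountTable,
    rna: CountTable,
    burned_sample_ids: Iterable[str],
) -> set[str]:
    """Taxa whose 16S rRNA:16S rRNA gene ratio is >= 1 over burned cores.

    The ratio is mean RNA relative abundance divided by mean DNA relative
    abundance across the burned retained 24-h samples (aggregate means,
    robust to sparse detection).  Taxa absent from the RNA table get ratio 0
    and are excluded; the boundary ratio 1 is kept.
    """
    shared = [s for s in burned_sample_ids if s in dna.sample_ids and s in rna.sample_ids]
    if not shared:
        raise ValidationError("no paired DNA/RNA burned samples for the viability filter")
    dna_sub = dna.subset_samples(shared)
    rna_sub = rna.subset_samples(shared)
    dna_mean = relative_abundance(dna_sub).mean(axis=1)
    rna_by_id = dict(zip(rna_sub.taxon_ids, relative_abundance(rna_sub).mean(axis=1)))
    viable: set[str] = set()
    for tid, d in zip(dna_sub.taxon_ids, dna_mean):
        r = rna_by_id.get(tid, 0.0)
        if d == 0 or r >= d:
            viable.add(tid)
    return viable


def effect_size_filter(results: Sequence[DiffAbundResult]) -> list[DiffAbundResult]:
    """Drop significant-but-small positive responses.

    The threshold is mean(log2fc) - sd(log2fc) over the given results (the
    significant positive responders of one experiment x horizon); results
    with log2fc below it are removed.  With fewer than two results, or zero
    spread, the filter is the identity.
    """
    if len(results) < 2:
        return list(results)
    lfcs = np.array([r.log2fc for r in results])
    threshold = lfcs.mean() - lfcs.std(ddof=1)
    return [r for r in results if r.log2fc >= threshold]


def _contrast_samples(
    contrast: str,
    samples_by_id: Mapping[str, SampleRecord],
    retained: set[str],
    horizon: Horizon,
) -> tuple[list[str], list[str], str]:
    """Sample ids for (group1, group0) of a contrast in one horizon, plus
    the timepoint key(s) needed from the tables."""
    def sel(tp: Timepoint, burned: bool) -> list[str]:
        return sorted(
            sid
            for sid in retained
            if (s := samples_by_id.get(sid)) is not None
            and s.timepoint is tp
            and s.horizon is horizon
            and s.burned == burned
        )

    if contrast == "survivor":
        return sel(Timepoint.T24H, True), sel(Timepoint.T24H, False), "t24h"
    if contrast == "fast_grower":
        return sel(Timepoint.T5WK, True), sel(Timepoint.T24H, True), "t5wk+t24h"
    if contrast == "postfire_affinity":
        return sel(Timepoint.T6MO, True), sel(Timepoint.T6MO, False), "t6mo"
    raise ValidationError(f"unknown contrast {contrast!r}")


@dataclass
class StageCounts:
    """Per-stage record counts for one contrast x horizon (run log)."""

    contrast: str
    horizon: str
    n_group1: int = 0
    n_group0: int = 0
    tested: int = 0
    significant: int = 0
    viability_passed: int | None = None
    effect_size_passed: int = 0


def call_trait(
    contrast: str,
    tables: Mapping[str, CountTable],
    samples: Sequence[SampleRecord],
    alpha_fdr: float = 0.05,
    temp_threshold_C: float = 50.0,
    min_prevalence: int = 3,
    apply_effect_size_filter: bool = True,
) -> tuple[list[TraitCall], list[StageCounts]]:
    """Run one trait-defining contrast over both horizons.

    ``tables`` maps timepoint keys to count tables and must contain
    ``dna_t24h`` (plus ``rna_t24h`` for the survivor contrast,
    ``dna_t5wk`` for fast growth, ``dna_t6mo`` for post-fire affinity).
    Returns the per-horizon-union trait calls plus per-stage counts.
    """
    required = {
        "survivor": ("dna_t24h", "rna_t24h"),
        "fast_grower": ("dna_t24h", "dna_t5wk"),
        "postfire_affinity": ("dna_t6mo",),
    }
    if contrast not in required:
        raise ValidationError(f"unknown contrast {contrast!r}")
    for key in required[contrast]:
        if key not in tables or tables[key] is None:
            raise ValidationError(f"contrast {contrast!r} needs the {key} table")

    samples_by_id = {s.sample_id: s for s in samples}
    retained = select_burn_exposed(samples, temp_threshold_C)
    calls: list[TraitCall] = []
    stage_log: list[StageCounts] = []

    for horizon in (Horizon.ORGANIC, Horizon.MINERAL):
        g1, g0, _ = _contrast_samples(contrast, samples_by_id, retained, horizon)
        log = StageCounts(contrast, horizon.value, len(g1), len(g0))
        stage_log.append(log)
        if not g1 or not g0:
            continue

        if contrast == "survivor":
            table = tables["dna_t24h"].subset_samples(g1 + g0)
        elif contrast == "postfire_affinity":
            table = tables["dna_t6mo"].subset_samples(g1 + g0)
        else:  # fast grower: burned cores at 5 wk (group 1) vs 24 h (group 0)
            t5 = tables["dna_t5wk"].subset_samples(g1)
            t24 = tables["dna_t24h"].subset_samples(g0)
            if t5.taxon_ids != t24.taxon_ids:
                raise ValidationError("t5wk and t24h tables must share taxa")
            table = CountTable(
                list(t5.taxon_ids), g1 + g0, np.column_stack([t5.counts, t24.counts])
            )

        group = np.array([1.0] * len(g1) + [0.0] * len(g0))
        ph = np.array([samples_by_id[s].pH for s in table.sample_ids])
        design = ContrastDesign(table.sample_ids, group, ph, table.sample_totals())
        results = fit_taxa(table.counts, table.taxon_ids, design, min_prevalence)
        log.tested = len(results)

        significant = [
            r for r in results if np.isfinite(r.q_value) and r.q_value < alpha_fdr and r.log2fc > 0
        ]
        log.significant = len(significant)

        if contrast == "survivor":
            burned_24h = [
                sid for sid in retained
                if (s := samples_by_id[sid]).burned
                and s.timepoint is Timepoint.T24H and s.horizon is horizon
            ]
            viable = viability_filter(tables["dna_t24h"], tables["rna_t24h"], burned_24h)
            significant = [r for r in significant if r.taxon_id in viable]
            log.viability_passed = len(significant)

        if apply_effect_size_filter:
            significant = effect_size_filter(significant)
        log.effect_size_passed = len(significant)

        calls.extend(
            TraitCall(r.taxon_id, contrast, horizon.value, r.log2fc, r.q_value)
            for r in significant
        )
    return calls, stage_log


def build_catalogue(per_trait_calls: Mapping[str, Sequence[TraitCall]]) -> TraitCatalogue:
    """Union the three contrasts into a catalogue; multi-trait taxa allowed."""
    cat = TraitCatalogue()
    for trait, calls in per_trait_calls.items():
        for c in calls:
            cat.entries.setdefault(c.taxon_id, set()).add(trait)
            cat.provenance.append(c)
    return cat
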