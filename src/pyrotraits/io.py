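"""Shared data model and readers/writers for the standard file formats.

Count tables are dense tab-separated files with taxa as rows and samples as
columns; sample metadata, copy-number predictions and flux series are CSV/TSV.
All readers accept UTF-8 with Unix or Windows line endings.  Missing metadata
values are encoded as empty cells; any other sentinel is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class TableKind(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Treatment(str, Enum):
    UNBURNED = "unburned"
    MOIST_BURN = "moist_burn"
    DRY_BURN = "dry_burn"


class Horizon(str, Enum):
    ORGANIC = "organic"
    MINERAL = "mineral"


class Timepoint(str, Enum):
    T24H = "t24h"
    T5WK = "t5wk"
    T6MO = "t6mo"
    FIELD = "field"


class Inoculation(str, Enum):
    NONE = "none"
    AUTOCLAVED_INOCULATED = "autoclaved_inoculated"
    INOCULATED_CONTROL = "inoculated_control"


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class CountTable:
    """Integer taxa x samples abundance matrix (DNA or RNA amplicon counts)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    kind: TableKind = TableKind.DNA

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (taxa x samples)")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        totals = self.counts.sum(axis=0)
        if np.any(totals < 1):
            empty = [s for s, t in zip(self.sample_ids, totals) if t < 1]
            raise ValidationError(f"empty sample columns rejected: {empty}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        cols = [idx[s] for s in sample_ids]
        return CountTable(
            list(self.taxon_ids), list(sample_ids), self.counts[:, cols], self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class TaxonRecord:
    """One ASV: identifier, representative sequence and predicted 16S rRNA
    gene copy number (copies per genome, >= 1)."""

    taxon_id: str
    sequence: str
    predicted_copy_number: float = 1.0
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"{self.taxon_id}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValidationError(
                f"{self.taxon_id}: sequence contains characters outside ACGT"
            )
        if not self.predicted_copy_number >= 1:
            raise ValidationError(
                f"{self.taxon_id}: predicted copy number must be >= 1"
            )


@dataclass
class SampleRecord:
    """Per-sample experimental metadata.

    Field samples carry a burn severity index on the 0-5 scale and years
    post-fire; lab burned cores carry the maximum thermocouple temperature
    used for the >50 degC exposure filter.
    """

    sample_id: str
    site_id: str
    treatment: Treatment
    horizon: Horizon
    timepoint: Timepoint
    inoculation: Inoculation = Inoculation.NONE
    pH: float = float("nan")
    max_temp_C: float | None = None
    vegetation: str = ""
    years_post_fire: int | None = None
    burn_severity_index: float | None = None
    qpcr_total_copies_per_g: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.treatment, str):
            self.treatment = Treatment(self.treatment)
        if isinstance(self.horizon, str):
            self.horizon = Horizon(self.horizon)
        if isinstance(self.timepoint, str):
            self.timepoint = Timepoint(self.timepoint)
        if isinstance(self.inoculation, str):
            self.inoculation = Inoculation(self.inoculation)
        is_field = self.timepoint is Timepoint.FIELD
        if is_field:
            if self.burn_severity_index is None or self.years_post_fire is None:
                raise ValidationError(
                    f"{self.sample_id}: field samples need burn_severity_index "
                    "and years_post_fire"
                )
            if not 0 <= self.burn_severity_index <= 5:
                raise ValidationError(
                    f"{self.sample_id}: burn_severity_index outside [0, 5]"
                )
        else:
            if self.burn_severity_index is not None or self.years_post_fire is not None:
                raise ValidationError(
                    f"{self.sample_id}: severity/years only valid for field samples"
                )

    @property
    def burned(self) -> bool:
        return self.treatment is not Treatment.UNBURNED


@dataclass
class FluxSeries:
    """CO2 efflux time series for one incubated core.

    Times in days (strictly increasing); fluxes in mg CO2-C per g initial
    total C per day.
    """

    sample_id: str
    times: np.ndarray
    fluxes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if self.times.shape != self.fluxes.shape or self.times.ndim != 1:
            raise ValidationError(
                f"{self.sample_id}: times and fluxes must be equal-length vectors"
            )
        if np.any(self.times < 0):
            raise ValidationError(f"{self.sample_id}: negative times")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.sample_id}: times must strictly increase")
        if np.any(self.fluxes < 0):
            raise ValidationError(f"{self.sample_id}: negative fluxes")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, kind: TableKind | str = TableKind.DNA) -> CountTable:
    """Read a dense TSV count table (rows = taxa, header = sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    sample_ids = [str(c) for c in df.columns]
    taxon_ids = [str(i) for i in df.index]
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path.name}: malformed numeric cell at row {taxon_ids[i]!r}, "
                    f"column {sample_ids[j]!r}: {raw!r}"
                ) from None
            if not value.is_integer():
                raise ValidationError(
                    f"{path.name}: non-integer count at row {taxon_ids[i]!r}, "
                    f"column {sample_ids[j]!r}: {raw!r}"
                )
            counts[i, j] = int(value)
    return CountTable(taxon_ids, sample_ids, counts, TableKind(kind))


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_taxa_fasta(path: str | Path, copy_number_path: str | Path) -> list[TaxonRecord]:
    """Read ASV representative sequences plus their predicted copy numbers.

    Every FASTA record must have a row in the copy-number TSV
    (columns: taxon_id, predicted_copy_number).
    """
    copies = pd.read_csv(copy_number_path, sep="\t", dtype={0: str})
    copies.columns = [c.strip() for c in copies.columns]
    id_col, cn_col = copies.columns[:2]
    copy_map = dict(zip(copies[id_col].astype(str), copies[cn_col].astype(float)))
    records = []
    missing = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if tid not in copy_map:
            missing.append(tid)
            continue
        records.append(TaxonRecord(tid, str(rec.seq), copy_map[tid]))
    if missing:
        raise ValidationError(
            f"taxa in FASTA missing from copy-number table: {missing}"
        )
    return records


def write_taxa_fasta(
    taxa: Iterable[TaxonRecord], fasta_path: str | Path, copy_number_path: str | Path | None = None
) -> None:
    taxa = list(taxa)
    with open(fasta_path, "w") as fh:
        for t in taxa:
            fh.write(f">{t.taxon_id}\n{t.sequence}\n")
    if copy_number_path is not None:
        pd.DataFrame(
            {
                "taxon_id": [t.taxon_id for t in taxa],
                "predicted_copy_number": [t.predicted_copy_number for t in taxa],
            }
        ).to_csv(copy_number_path, sep="\t", index=False)


_METADATA_COLUMNS = [
    "sample_id",
    "site_id",
    "treatment",
    "horizon",
    "timepoint",
    "inoculation",
    "pH",
    "max_temp_C",
    "vegetation",
    "years_post_fire",
    "burn_severity_index",
    "qpcr_total_copies_per_g",
]


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata CSV; empty cells encode missing values."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        def opt_float(key: str) -> float | None:
            raw = row.get(key, "")
            if raw == "":
                return None
            try:
                return float(raw)
            except ValueError:
                raise ValidationError(
                    f"sample {row['sample_id']}: bad value for {key}: {raw!r}"
                ) from None

        years = opt_float("years_post_fire")
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                site_id=row["site_id"],
                treatment=Treatment(row["treatment"]),
                horizon=Horizon(row["horizon"]),
                timepoint=Timepoint(row["timepoint"]),
                inoculation=Inoculation(row.get("inoculation", "none") or "none"),
                pH=opt_float("pH") if row.get("pH", "") != "" else float("nan"),
                max_temp_C=opt_float("max_temp_C"),
                vegetation=row.get("vegetation", ""),
                years_post_fire=int(years) if years is not None else None,
                burn_severity_index=opt_float("burn_severity_index"),
                qpcr_total_copies_per_g=opt_float("qpcr_total_copies_per_g"),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in metadata")
    return records


def write_sample_metadata(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "site_id": s.site_id,
                "treatment": s.treatment.value,
                "horizon": s.horizon.value,
                "timepoint": s.timepoint.value,
                "inoculation": s.inoculation.value,
                "pH": "" if math.isnan(s.pH) else s.pH,
                "max_temp_C": "" if s.max_temp_C is None else s.max_temp_C,
                "vegetation": s.vegetation,
                "years_post_fire": "" if s.years_post_fire is None else s.years_post_fire,
                "burn_severity_index": ""
                if s.burn_severity_index is None
                else s.burn_severity_index,
                "qpcr_total_copies_per_g": ""
                if s.qpcr_total_copies_per_g is None
                else s.qpcr_total_copies_per_g,
            }
        )
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, index=False)


def read_flux_csv(path: str | Path) -> list[FluxSeries]:
    """Read a long-format flux CSV (sample_id, time_days, flux)."""
    df = pd.read_csv(path)
    series = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_days")
        series.append(
            FluxSeries(str(sid), grp["time_days"].to_numpy(), grp["flux"].to_numpy())
        )
    return series


def write_flux_csv(series: Iterable[FluxSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"sample_id": s.sample_id, "time_days": s.times, "flux": s.fluxes})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def join_metadata(table: CountTable, samples: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    """Exact sample_id join; any table sample without metadata is an error."""
    by_id = {s.sample_id: s for s in samples}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples in count table lack metadata: {missing}")
    return {s: by_id[s] for s in table.sample_ids}


# ---------------------------------------------------------------------------
# small numeric operations on the data model


def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-column proportions; each sample column sums to 1."""
    totals = table.counts.sum(axis=0).astype(float)
    return table.counts / totals[np.newaxis, :]


def radiant_exposure(intensity_kW_m2: float, duration_s: float) -> float:
    """Cumulative radiant energy (MJ m^-2) delivered by a burn protocol.

    A constant radiant heat flux of ``intensity_kW_m2`` applied for
    ``duration_s`` seconds delivers intensity x duration kJ m^-2, i.e.
    intensity x duration / 1000 MJ m^-2.
    """
    if intensity_kW_m2 < 0 or duration_s < 0:
        raise ValidationError("intensity and duration must be non-negative")
    return intensity_kW_m2 * duration_s / 1000.0
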