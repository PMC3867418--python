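"""Data model and I/O for RT-qPCR Cq tables, cohort sheets and miRNA panels.

The central container is :class:`CqDataset`: a miRNA panel (with organ-system
enrichment classes), a cohort of subjects (control or named pathology, with
organ-system and pathology-type labels), and a long table of per-replicate
quantification-cycle (Cq) measurements. Technical replicates are collapsed to
one consensus Cq per (subject, miRNA) by :func:`aggregate_replicates`; all
downstream analysis (pair ratios, screening, classification) runs on the
consensus values.

Conventions
-----------
* Cq values at or above ``max_cycles`` (default 40) are non-detects and are
  treated as missing, never as numeric.
* ``"NA"`` and the empty string are silent missing tokens; any other
  unparseable Cq cell (e.g. the instrument's ``"Undetermined"``) also becomes
  missing but increments the dataset's parse-warning counter.
* Files are comma-separated UTF-8 with a header row and ``.`` decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

ENRICHMENT_CLASSES = ("gi_enriched", "pulmonary_enriched", "ubiquitous", "disease_associated")
ORGAN_SYSTEMS = ("gi", "pulmonary", "none")
PATHOLOGY_TYPES = ("cancer", "inflammation", "none")

#: Missing tokens accepted silently in Cq cells.
_SILENT_MISSING = {"", "NA"}

DEFAULT_MAX_CYCLES = 40.0


@dataclass(frozen=True)
class MiRNA:
    """One panel member: a miRNA and its tissue-enrichment class."""

    name: str
    enrichment_class: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("miRNA name must be nonempty")
        if self.enrichment_class not in ENRICHMENT_CLASSES:
            raise ValidationError(
                f"unknown enrichment class {self.enrichment_class!r} for {self.name}; "
                f"expected one of {ENRICHMENT_CLASSES}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member and its group labels.

    Controls carry ``organ_system='none'`` and ``pathology_type='none'``;
    disease subjects must have both set.
    """

    subject_id: str
    group: str
    organ_system: str = "none"
    pathology_type: str = "none"
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be nonempty")
        if self.organ_system not in ORGAN_SYSTEMS:
            raise ValidationError(f"unknown organ_system {self.organ_system!r}")
        if self.pathology_type not in PATHOLOGY_TYPES:
            raise ValidationError(f"unknown pathology_type {self.pathology_type!r}")
        is_disease = self.organ_system != "none" or self.pathology_type != "none"
        if is_disease and ("none" in (self.organ_system, self.pathology_type)):
            raise ValidationError(
                f"subject {self.subject_id}: disease subjects need both organ_system "
                "and pathology_type; controls need neither"
            )

    @property
    def is_control(self) -> bool:
        return self.organ_system == "none" and self.pathology_type == "none"


@dataclass
class CqDataset:
    """Panel + cohort + long-format replicate Cq measurements.

    ``measurements`` has columns ``subject_id, mirna, replicate, cq`` (one row
    per technical replicate; ``cq`` is NaN when missing). ``aggregated`` is the
    subject x miRNA consensus matrix, present only after
    :func:`aggregate_replicates`.
    """

    panel: list[MiRNA]
    subjects: list[SubjectRecord]
    measurements: pd.DataFrame
    aggregated: pd.DataFrame | None = None
    parse_warnings: int = 0

    # -- convenience lookups -------------------------------------------------
    @property
    def mirna_names(self) -> list[str]:
        return [m.name for m in self.panel]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subjects_frame(self) -> pd.DataFrame:
        """Cohort sheet as a DataFrame indexed by subject_id."""
        return pd.DataFrame(
            {
                "group": [s.group for s in self.subjects],
                "organ_system": [s.organ_system for s in self.subjects],
                "pathology_type": [s.pathology_type for s in self.subjects],
            },
            index=pd.Index(self.subject_ids, name="subject_id"),
        )

    def panel_classes(self) -> dict[str, str]:
        return {m.name: m.enrichment_class for m in self.panel}

    def validate(self) -> None:
        """Check referential integrity and uniqueness contracts."""
        names = self.mirna_names
        if len(set(names)) != len(names):
            raise ValidationError("duplicate miRNA names in panel")
        sids = self.subject_ids
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate subject_ids in cohort")
        if self.measurements.empty:
            raise ValidationError("empty dataset: no Cq measurements")
        unknown_m = set(self.measurements["mirna"]) - set(names)
        if unknown_m:
            raise ValidationError(f"measurements reference unknown miRNA(s): {sorted(unknown_m)}")
        unknown_s = set(self.measurements["subject_id"]) - set(sids)
        if unknown_s:
            raise ValidationError(f"measurements reference unknown subject(s): {sorted(unknown_s)}")
        dup = self.measurements.duplicated(["subject_id", "mirna", "replicate"])
        if dup.any():
            row = self.measurements[dup].iloc[0]
            raise ValidationError(
                "duplicate replicate for "
                f"(subject={row['subject_id']}, mirna={row['mirna']}, replicate={row['replicate']})"
            )
        cq = self.measurements["cq"]
        finite = cq.dropna()
        if ((finite < 0) | ~np.isfinite(finite)).any():
            raise ValidationError("non-missing Cq values must be finite and >= 0")


def _parse_cq_column(raw: pd.Series, max_cycles: float) -> tuple[pd.Series, int]:
    """Parse Cq strings to floats; return (values, parse_warning_count).

    Silent missing tokens become NaN without a warning; any other unparseable
    cell (e.g. "Undetermined") becomes NaN and counts as a warning. Numeric
    values >= max_cycles are non-detects -> NaN (no warning).
    """
    text = raw.astype("string").fillna("").str.strip()
    numeric = pd.to_numeric(text, errors="coerce")
    unparsed = numeric.isna() & ~text.isin(_SILENT_MISSING)
    warnings = int(unparsed.sum())
    out = numeric.astype(float)
    out[out >= max_cycles] = np.nan
    return out, warnings


def read_panel(path: str | Path) -> list[MiRNA]:
    """Read a panel CSV with columns ``mirna, enrichment_class[, notes]``."""
    df = _read_csv(path)
    _require_columns(df, ["mirna", "enrichment_class"], path)
    notes = df["notes"] if "notes" in df.columns else [""] * len(df)
    return [
        MiRNA(str(n), str(c).strip(), str(t) if not pd.isna(t) else "")
        for n, c, t in zip(df["mirna"], df["enrichment_class"], notes)
    ]


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV with columns ``subject_id, group, organ_system, pathology_type``.

    Any further columns are kept as string covariates.
    """
    df = _read_csv(path)
    _require_columns(df, ["subject_id", "group", "organ_system", "pathology_type"], path)
    extra = [c for c in df.columns if c not in ("subject_id", "group", "organ_system", "pathology_type")]
    records = []
    for _, row in df.iterrows():
        cov = {c: str(row[c]) for c in extra if not pd.isna(row[c])}
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                organ_system=str(row["organ_system"]).strip(),
                pathology_type=str(row["pathology_type"]).strip(),
                covariates=cov,
            )
        )
    return records


def read_cq_table(
    path: str | Path,
    panel_path: str | Path,
    cohort_path: str | Path,
    max_cycles: float = DEFAULT_MAX_CYCLES,
) -> CqDataset:
    """Assemble and validate a :class:`CqDataset` from the three CSV inputs.

    The Cq file is long format with header ``subject_id, mirna, replicate, cq``.
    Unknown miRNAs/subjects and duplicate replicate keys raise
    :class:`ValidationError`; unparseable Cq cells become missing and are
    counted in ``parse_warnings``.
    """
    panel = read_panel(panel_path)
    subjects = read_cohort(cohort_path)
    df = _read_csv(path)
    _require_columns(df, ["subject_id", "mirna", "replicate", "cq"], path)
    cq, warnings = _parse_cq_column(df["cq"], max_cycles)
    measurements = pd.DataFrame(
        {
            "subject_id": df["subject_id"].astype(str),
            "mirna": df["mirna"].astype(str),
            "replicate": pd.to_numeric(df["replicate"], errors="raise").astype(int),
            "cq": cq,
        }
    )
    ds = CqDataset(panel=panel, subjects=subjects, measurements=measurements, parse_warnings=warnings)
    ds.validate()
    return ds


def aggregate_replicates(
    ds: CqDataset, method: str = "median", min_replicates: int = 2
) -> CqDataset:
    """Collapse technical replicates to one consensus Cq per (subject, miRNA).

    Cells with fewer than ``min_replicates`` non-missing replicates are marked
    missing. Returns a new dataset; the input is untouched.
    """
    if method not in ("median", "mean"):
        raise ValidationError(f"aggregation method must be 'median' or 'mean', got {method!r}")
    if min_replicates < 1:
        raise ValidationError("min_replicates must be >= 1")
    ds.validate()
    grouped = ds.measurements.groupby(["subject_id", "mirna"])["cq"]
    agg = grouped.agg(method)
    counts = grouped.count()
    agg[counts < min_replicates] = np.nan
    wide = agg.unstack("mirna")
    # full subject x panel grid, stable order
    wide = wide.reindex(index=ds.subject_ids, columns=ds.mirna_names)
    wide.index.name = "subject_id"
    return replace(ds, aggregated=wide)


# ---------------------------------------------------------------------------
# writers


def format_float(x: float) -> str:
    """Render a float with 6 significant digits (missing -> 'NA')."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


def write_results_table(results: Iterable, path: str | Path) -> None:
    """Write screening results as CSV, sorted by ascending p-value.

    One row per pair with columns ``numerator, denominator, n_case, n_control,
    U, p_value, bonferroni_alpha, significant, auc, cutoff, sensitivity,
    specificity, accuracy``. Ties in p are broken by pair label. Refuses to
    write an empty table.
    """
    results = list(results)
    if not results:
        raise ValidationError("refusing to write an empty results table")
    rows = []
    for r in results:
        rows.append(
            {
                "numerator": r.pair[0],
                "denominator": r.pair[1],
                "n_case": r.n_case,
                "n_control": r.n_control,
                "U": format_float(r.u_statistic),
                "p_value": format_float(r.p_value),
                "bonferroni_alpha": format_float(r.bonferroni_alpha),
                "significant": r.significant,
                "auc": format_float(r.auc),
                "cutoff": format_float(r.cutoff),
                "sensitivity": format_float(r.sensitivity),
                "specificity": format_float(r.specificity),
                "accuracy": format_float(r.accuracy),
                "_p": r.p_value if r.p_value == r.p_value else np.inf,
                "_label": f"{r.pair[0]}/{r.pair[1]}",
            }
        )
    df = pd.DataFrame(rows).sort_values(["_p", "_label"], kind="mergesort")
    df = df.drop(columns=["_p", "_label"])
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write results table to {path}: {exc}") from exc


def write_cohort_files(ds: CqDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset back to the three-CSV on-disk layout.

    Produces ``cq.csv`` (long replicate table), ``cohort.csv`` and
    ``panel.csv`` under ``directory``; returns the paths. Cq values are printed
    with 6 significant digits, so a write/read round trip reproduces every
    non-missing value bit-identically on the printed representation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cq": directory / "cq.csv",
        "cohort": directory / "cohort.csv",
        "panel": directory / "panel.csv",
    }
    meas = ds.measurements.copy()
    meas["cq"] = [format_float(v) for v in meas["cq"]]
    meas.to_csv(paths["cq"], index=False)
    pd.DataFrame(
        {
            "subject_id": ds.subject_ids,
            "group": [s.group for s in ds.subjects],
            "organ_system": [s.organ_system for s in ds.subjects],
            "pathology_type": [s.pathology_type for s in ds.subjects],
        }
    ).to_csv(paths["cohort"], index=False)
    pd.DataFrame(
        {
            "mirna": ds.mirna_names,
            "enrichment_class": [m.enrichment_class for m in ds.panel],
            "notes": [m.notes for m in ds.panel],
        }
    ).to_csv(paths["panel"], index=False)
    return paths


# ---------------------------------------------------------------------------
# helpers


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    # keep Cq cells as raw strings; missing-token handling is ours
    return pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
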