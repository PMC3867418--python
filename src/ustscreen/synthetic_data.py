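"""Synthetic RT-qPCR cohorts with the structure the pair-ratio analysis assumes.

The generative model is deliberately the simplest one that captures why
within-subject ratios are the right normalization for circulating-miRNA
RT-qPCR data::

    Cq(subject s, miRNA m, replicate r) =
        baseline_m + offset_s + effect_{group(s), m} + eps_{s,m,r}

* ``baseline_m`` — the panel-wide mean Cq of miRNA m (organ-enriched miRNAs
  circulate at lower abundance, hence higher Cq, than ubiquitous ones);
* ``offset_s ~ N(0, subject_offset_sd)`` — a per-subject global shift standing
  in for extraction yield and RT-qPCR inhibition, the nuisance that single
  miRNA levels cannot escape and that cancels exactly in every pair ratio;
* ``effect_{g,m}`` — an additive Cq shift for a disease group (negative =
  elevated plasma concentration; one cycle = two-fold);
* ``eps ~ N(0, noise_sd)`` — per-replicate technical noise.

Cq values reaching the detection limit (``dropout_cq``, default 40 cycles)
become missing. Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .panel_io import CqDataset, MiRNA, SubjectRecord

# Default panel: 17 circulating miRNAs with literature-reported organ
# enrichment (6 GI-enriched, 6 pulmonary-enriched, 3 ubiquitous,
# 2 cancer/inflammation-associated). The assay format nominally holds 18
# slots; the 18th is left to the caller to configure.
DEFAULT_PANEL: tuple[MiRNA, ...] = (
    MiRNA("miR-145", "gi_enriched"),
    MiRNA("miR-148a", "gi_enriched"),
    MiRNA("miR-192", "gi_enriched"),
    MiRNA("miR-194", "gi_enriched"),
    MiRNA("miR-203", "gi_enriched"),
    MiRNA("miR-215", "gi_enriched"),
    MiRNA("miR-34b", "pulmonary_enriched"),
    MiRNA("miR-142-5p", "pulmonary_enriched"),
    MiRNA("miR-146b-5p", "pulmonary_enriched"),
    MiRNA("miR-155", "pulmonary_enriched"),
    MiRNA("miR-223", "pulmonary_enriched"),
    MiRNA("miR-486-5p", "pulmonary_enriched"),
    MiRNA("miR-30e-3p", "ubiquitous"),
    MiRNA("miR-181a", "ubiquitous"),
    MiRNA("miR-409-3p", "ubiquitous"),
    MiRNA("miR-126", "disease_associated"),
    MiRNA("miR-31", "disease_associated"),
)

#: Mean Cq per miRNA (cycles). Ubiquitous miRNAs are abundant (low Cq);
#: organ-enriched ones are scarce in plasma (high Cq). Range 26-34.
DEFAULT_BASELINES: dict[str, float] = {
    "miR-145": 31.0,
    "miR-148a": 30.5,
    "miR-192": 30.0,
    "miR-194": 31.5,
    "miR-203": 32.0,
    "miR-215": 32.5,
    "miR-34b": 33.0,
    "miR-142-5p": 30.5,
    "miR-146b-5p": 31.0,
    "miR-155": 31.5,
    "miR-223": 30.0,
    "miR-486-5p": 32.0,
    "miR-30e-3p": 26.5,
    "miR-181a": 27.0,
    "miR-409-3p": 27.5,
    "miR-126": 28.0,
    "miR-31": 29.0,
}


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    ``effects`` maps ``(group, mirna) -> dCq shift`` in cycles (negative =
    elevated concentration); ``group_meta`` maps each group to its
    ``(organ_system, pathology_type)`` labels (controls: ``("none","none")``).
    """

    panel: tuple[MiRNA, ...] = DEFAULT_PANEL
    baselines: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    subject_offset_sd: float = 1.0
    noise_sd: float = 0.25
    replicates: int = 3
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 30, "disease": 10}
    )
    group_meta: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"control": ("none", "none"), "disease": ("gi", "cancer")}
    )
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dropout_cq: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        names = [m.name for m in self.panel]
        if len(names) < 2 or len(set(names)) != len(names):
            raise ValidationError("panel must hold >= 2 uniquely named miRNAs")
        missing_b = set(names) - set(self.baselines)
        if missing_b:
            raise ValidationError(f"baselines missing for: {sorted(missing_b)}")
        if self.subject_offset_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValidationError(f"group {g!r} size must be >= 1")
            if g not in self.group_meta:
                raise ValidationError(f"group {g!r} has no organ_system/pathology_type metadata")
        for (g, m), _ in self.effects.items():
            if g not in self.group_sizes:
                raise ValidationError(f"effect references undeclared group {g!r}")
            if m not in names:
                raise ValidationError(f"effect references miRNA {m!r} absent from panel")

    # -- plain-dict form for YAML/JSON configs ------------------------------
    def to_dict(self) -> dict:
        return {
            "panel": [{"name": m.name, "enrichment_class": m.enrichment_class} for m in self.panel],
            "baselines": dict(self.baselines),
            "subject_offset_sd": self.subject_offset_sd,
            "noise_sd": self.noise_sd,
            "replicates": self.replicates,
            "group_sizes": dict(self.group_sizes),
            "group_meta": {g: list(v) for g, v in self.group_meta.items()},
            "effects": _effects_to_nested(self.effects),
            "dropout_cq": self.dropout_cq,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        if "panel" in kwargs:
            kwargs["panel"] = tuple(
                MiRNA(p["name"], p["enrichment_class"], p.get("notes", "")) for p in kwargs["panel"]
            )
        if "group_meta" in kwargs:
            kwargs["group_meta"] = {g: tuple(v) for g, v in kwargs["group_meta"].items()}
        if "effects" in kwargs:
            kwargs["effects"] = _effects_from_nested(kwargs["effects"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _effects_to_nested(effects) -> dict:
    nested: dict[str, dict[str, float]] = {}
    for (g, m), v in effects.items():
        nested.setdefault(g, {})[m] = float(v)
    return nested


def _effects_from_nested(nested) -> dict:
    if nested and isinstance(next(iter(nested.keys()), None), tuple):
        return dict(nested)
    return {(g, m): float(v) for g, inner in nested.items() for m, v in inner.items()}


def simulate_cohort(cfg: SimulationConfig) -> CqDataset:
    """Draw one replicate-level cohort from the generative model.

    Returns an unaggregated, validated :class:`CqDataset`; bit-identical
    datasets result from identical configs (including the seed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = [m.name for m in cfg.panel]
    baselines = np.array([cfg.baselines[m] for m in names])

    subjects: list[SubjectRecord] = []
    for group, n in cfg.group_sizes.items():
        organ, ptype = cfg.group_meta[group]
        for i in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}_{i + 1:03d}",
                    group=group,
                    organ_system=organ,
                    pathology_type=ptype,
                )
            )

    n_sub, n_mir, n_rep = len(subjects), len(names), cfg.replicates
    offsets = rng.normal(0.0, cfg.subject_offset_sd, size=n_sub)
    effects = np.zeros((n_sub, n_mir))
    for j, m in enumerate(names):
        for i, s in enumerate(subjects):
            effects[i, j] = cfg.effects.get((s.group, m), 0.0)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_sub, n_mir, n_rep))
    cq = baselines[None, :, None] + offsets[:, None, None] + effects[:, :, None] + noise
    cq = np.where(cq >= cfg.dropout_cq, np.nan, cq)

    measurements = pd.DataFrame(
        {
            "subject_id": np.repeat([s.subject_id for s in subjects], n_mir * n_rep),
            "mirna": np.tile(np.repeat(names, n_rep), n_sub),
            "replicate": np.tile(np.arange(1, n_rep + 1), n_sub * n_mir),
            "cq": cq.reshape(-1),
        }
    )
    ds = CqDataset(panel=list(cfg.panel), subjects=subjects, measurements=measurements)
    ds.validate()
    return ds


def null_cohort(cfg: SimulationConfig) -> CqDataset:
    """Same cohort layout with every disease effect zeroed (group labels kept)."""
    return simulate_cohort(replace(cfg, effects={}))


# group -> (organ_system, pathology_type) for the demonstration scenario
_DEMO_META = {
    "control": ("none", "none"),
    "esophageal_cancer": ("gi", "cancer"),
    "gastric_cancer": ("gi", "cancer"),
    "colon_cancer": ("gi", "cancer"),
    "crohns_disease": ("gi", "inflammation"),
    "asthma": ("pulmonary", "inflammation"),
    "pneumonia": ("pulmonary", "inflammation"),
    "nsclc": ("pulmonary", "cancer"),
}

# dCq shifts (cycles; negative = elevated in plasma) applied to every group of
# the matching category. 2 cycles = 4-fold concentration change.
_GI_EFFECTS = {"miR-215": -2.0, "miR-203": -2.0, "miR-192": -1.5, "miR-194": -1.5, "miR-148a": -1.0}
_PULMONARY_EFFECTS = {"miR-486-5p": -2.0, "miR-34b": -2.0, "miR-142-5p": -1.5, "miR-223": -1.5}
_CANCER_EFFECTS = {"miR-126": -2.0, "miR-31": -2.0}
_INFLAMMATION_EFFECTS = {"miR-155": -2.0, "miR-146b-5p": -1.5}


def demo_scenario(seed: int = 0) -> SimulationConfig:
    """The shipped demonstration scenario: 7 disease groups of 10 + 30 controls.

    Four GI-system groups (stage I/II esophageal, gastric and colon cancers,
    Crohn's disease) and three pulmonary-system groups (asthma, pneumonia,
    NSCLC), 10 subjects each, with one shared 30-subject control group —
    100 subjects in total. Each disease group receives its organ system's
    shifts on organ-enriched miRNAs plus its pathology type's shifts on
    cancer/inflammation-associated miRNAs. Effect sizes are demonstrative
    (chosen for clear signal at this cohort size), not estimates of real
    plasma changes.
    """
    group_sizes = {g: (30 if g == "control" else 10) for g in _DEMO_META}
    effects: dict[tuple[str, str], float] = {}
    for group, (organ, ptype) in _DEMO_META.items():
        if organ == "gi":
            shifts = _GI_EFFECTS
        elif organ == "pulmonary":
            shifts = _PULMONARY_EFFECTS
        else:
            shifts = {}
        for m, v in shifts.items():
            effects[(group, m)] = v
        type_shifts = (
            _CANCER_EFFECTS if ptype == "cancer"
            else _INFLAMMATION_EFFECTS if ptype == "inflammation"
            else {}
        )
        for m, v in type_shifts.items():
            effects[(group, m)] = v
    cfg = SimulationConfig(
        group_sizes=group_sizes,
        group_meta=dict(_DEMO_META),
        effects=effects,
        seed=seed,
    )
    cfg.validate()
    return cfg
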