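"""Synthetic two-block time-course generator with planted signals.

Emulates the structure of a cold-storage chilling-injury study: three
treatments (untreated control, the antioxidant DPA, and the ethylene
perception inhibitor 1-MCP), eight storage-day sampling points, and
three biological replicates per cell.  Day-0 samples describe the
pre-treatment state and are generated once, then shared across
treatments.

Planted signals define the ground truth every downstream stage is
tested against:

* ``biphasic_early`` -- a CTOL-like oxidative-stress marker that rises
  from an onset day to a mid-storage peak and then declines;
* ``sigmoidal_late`` -- a methanol-like symptomatic marker, exactly at
  baseline before its onset day and rising logistically afterwards;
* ``monotone_ripening`` -- a background ripening trend;
* ``noise`` -- no planted structure.

Abundances are log-normal: log2(value) = baseline + amplitude * curve(day)
* treatment multiplier + N(0, noise_sd).  All entities linked to one
signal share the same amplitude, so at vanishing noise every linked gene
is exactly proportional to the signal's metabolite trace (r^2 = 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import OmicsBlock
from .errors import SizingError, ValidationError

DEFAULT_DAYS = (0, 7, 14, 28, 61, 92, 123, 183)
DEFAULT_TREATMENTS = ("control", "DPA", "MCP")
SIGNAL_KINDS = ("biphasic_early", "sigmoidal_late", "monotone_ripening", "noise")
NOISE_LABEL = "noise"


def default_scald_trajectory(
    treatments: Sequence[str] = DEFAULT_TREATMENTS,
    days: Sequence[int] = DEFAULT_DAYS,
) -> dict[tuple[str, int], int]:
    """Expected ordinal scald score per (treatment, day).

    Control fruit develop symptoms after ~2 months, reaching severe
    coverage by 6 months; DPA-treated fruit show only minor symptoms at
    6 months; 1-MCP-treated fruit never develop symptoms.
    """
    out: dict[tuple[str, int], int] = {}
    for t in treatments:
        for d in days:
            if t == "MCP":
                score = 1
            elif t == "DPA":
                score = 2 if d >= 183 else 1
            else:  # control
                if d < 92:
                    score = 1
                elif d < 123:
                    score = 2
                elif d < 183:
                    score = 3
                else:
                    score = 4
            out[(t, d)] = score
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Treatments x storage days x replicates, plus the scald trajectory."""

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates_per_cell: int = 3
    scald_trajectory: Mapping[tuple[str, int], int] | None = None

    def __post_init__(self) -> None:
        if len(self.days) < 2 or self.days[0] != 0:
            raise ValidationError("days must start at 0")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError("days must be strictly increasing")
        if self.replicates_per_cell < 1:
            raise ValidationError("replicates_per_cell must be >= 1")
        traj = self.scald_trajectory
        if traj is None:
            traj = default_scald_trajectory(self.treatments, self.days)
            object.__setattr__(self, "scald_trajectory", traj)
        for t in self.treatments:
            prev = None
            for d in self.days:
                score = traj[(t, d)]
                if score not in (1, 2, 3, 4):
                    raise ValidationError(
                        f"scald score {score} for ({t}, {d}) outside 1-4"
                    )
                if prev is not None and score < prev:
                    raise ValidationError(
                        f"scald must be non-decreasing over days ({t})"
                    )
                prev = score

    @property
    def n_observations(self) -> int:
        return len(self.treatments) * len(self.days) * self.replicates_per_cell


def scald_scores(design: StudyDesign) -> pd.DataFrame:
    """Tabulate the (treatment, day) -> scald score trajectory."""
    rows = [
        (t, d, design.scald_trajectory[(t, d)])
        for t in design.treatments
        for d in design.days
    ]
    return pd.DataFrame(rows, columns=["treatment", "day", "scald"])


@dataclass(frozen=True)
class PlantedSignal:
    """One latent temporal signal with its linked genes and metabolites.

    ``gene_clusters`` maps a planted cluster id to the number of member
    genes; ``metabolite_ids`` names the metabolites carrying the trace.
    ``amplitude`` is the log2 fold change at full curve height; the
    treatment multipliers (in [0, 1]) scale it per treatment.
    """

    name: str
    kind: str
    onset_day: int = 0
    peak_day: int | None = None
    tau: float = 45.0
    amplitude: float = 3.0
    treatment_multipliers: Mapping[str, float] = field(default_factory=dict)
    gene_clusters: Mapping[str, int] = field(default_factory=dict)
    metabolite_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValidationError(f"unknown signal kind '{self.kind}'")
        if self.kind == "biphasic_early":
            if self.peak_day is None or self.peak_day <= self.onset_day:
                raise ValidationError(
                    "biphasic signals need peak_day > onset_day"
                )
        for t, m in self.treatment_multipliers.items():
            if not 0.0 <= m <= 1.0:
                raise ValidationError(
                    f"multiplier for '{t}' must be in [0, 1], got {m}"
                )

    def n_genes(self) -> int:
        return sum(self.gene_clusters.values())

    def curve(self, day: float, max_day: float) -> float:
        """Unit-height temporal profile of the signal at ``day``."""
        if self.kind == "biphasic_early":
            if day <= self.onset_day:
                return 0.0
            if day <= self.peak_day:
                return (day - self.onset_day) / (self.peak_day - self.onset_day)
            if max_day <= self.peak_day:
                return 1.0
            return max(0.0, 1.0 - (day - self.peak_day) / (max_day - self.peak_day))
        if self.kind == "sigmoidal_late":
            if day <= self.onset_day:
                return 0.0
            # logistic ramp anchored at exactly 0 at onset
            return 2.0 / (1.0 + math.exp(-(day - self.onset_day) / self.tau)) - 1.0
        if self.kind == "monotone_ripening":
            return day / max_day
        return 0.0


def default_signals() -> list[PlantedSignal]:
    """The study conditions the generator emulates by default.

    A CTOL-like biphasic oxidative marker (onset ~2 weeks, mid-storage
    peak, suppressed by DPA/1-MCP), a methanol-like late symptomatic
    marker rising after two months essentially only in control fruit
    (mirrored by methyl esters), and a monotone ripening background
    attenuated by 1-MCP.
    """
    return [
        PlantedSignal(
            name="ctol",
            kind="biphasic_early",
            onset_day=14,
            peak_day=61,
            amplitude=3.0,
            treatment_multipliers={"control": 1.0, "DPA": 0.15, "MCP": 0.1},
            gene_clusters={"ctol_cluster": 60},
            metabolite_ids=(
                "CTOL",
                "farnesene_oxide_1",
                "farnesene_oxide_2",
                "MHO",
                "triterpenoid_ox_1",
                "triterpenoid_ox_2",
            ),
        ),
        PlantedSignal(
            name="methanol",
            kind="sigmoidal_late",
            onset_day=61,
            tau=45.0,
            amplitude=3.0,
            treatment_multipliers={"control": 1.0, "DPA": 0.05, "MCP": 0.0},
            gene_clusters={"pme_cluster": 90},
            metabolite_ids=(
                "methanol",
                "methyl_acetate",
                "methyl_propanoate",
                "methyl_butyrate",
                "methyl_2_methylbutyrate",
                "methyl_hexanoate",
            ),
        ),
        PlantedSignal(
            name="ripening",
            kind="monotone_ripening",
            amplitude=2.0,
            treatment_multipliers={"control": 1.0, "DPA": 0.9, "MCP": 0.35},
            gene_clusters={"ripening_cluster": 80},
            metabolite_ids=(
                "alpha_farnesene",
                "hexyl_acetate",
                "butyl_acetate",
                "hexanol",
            ),
        ),
    ]


def default_design() -> StudyDesign:
    return StudyDesign()


@dataclass
class GroundTruth:
    """What was planted: labels linking every entity to its signal."""

    signals: list[PlantedSignal]
    gene_labels: dict[str, str]  # gene -> planted cluster id or "noise"
    metabolite_labels: dict[str, str]  # metabolite -> signal name or "noise"
    cluster_signal: dict[str, str]  # planted cluster id -> signal name
    cluster_bins: dict[str, str]  # planted cluster id -> annotation bin
    noise_sd: float
    seed: int

    def genes_of_cluster(self, cluster_id: str) -> list[str]:
        return [g for g, c in self.gene_labels.items() if c == cluster_id]

    def genes_of_signal(self, signal_name: str) -> list[str]:
        clusters = {c for c, s in self.cluster_signal.items() if s == signal_name}
        return [g for g, c in self.gene_labels.items() if c in clusters]

    def to_dict(self) -> dict:
        return {
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "signals": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "onset_day": s.onset_day,
                    "peak_day": s.peak_day,
                    "tau": s.tau,
                    "amplitude": s.amplitude,
                    "treatment_multipliers": dict(s.treatment_multipliers),
                    "gene_clusters": dict(s.gene_clusters),
                    "metabolite_ids": list(s.metabolite_ids),
                }
                for s in self.signals
            ],
            "gene_labels": self.gene_labels,
            "metabolite_labels": self.metabolite_labels,
            "cluster_signal": self.cluster_signal,
            "cluster_bins": self.cluster_bins,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _observation_keys(design: StudyDesign) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample table plus the map from sample id to distinct-observation
    column (day-0 replicates are one observation shared by all treatments)."""
    rows = []
    for t in design.treatments:
        for d in design.days:
            for r in range(1, design.replicates_per_cell + 1):
                sid = f"{t}_d{d:03d}_r{r}"
                rows.append(
                    (sid, t, d, r, design.scald_trajectory[(t, d)])
                )
    meta = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "day", "replicate", "scald"]
    )
    obs_index: dict[str, int] = {}
    key_to_col: dict[tuple, int] = {}
    for sid, t, d, r in zip(meta["sample_id"], meta["treatment"], meta["day"], meta["replicate"]):
        key = ("harvest", r) if d == 0 else (t, d, r)
        if key not in key_to_col:
            key_to_col[key] = len(key_to_col)
        obs_index[sid] = key_to_col[key]
    return meta, obs_index


def generate_dataset(
    design: StudyDesign | None = None,
    n_genes: int = 2000,
    n_metabolites: int = 120,
    signals: Sequence[PlantedSignal] | None = None,
    noise_sd: float = 0.25,
    seed: int = 7,
    baseline_log2_range: tuple[float, float] = (3.0, 9.0),
) -> tuple[OmicsBlock, OmicsBlock, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate expression and metabolite blocks with planted structure.

    Returns (expression block, metabolite block, sample metadata,
    annotation table, ground truth).  Identical arguments give bitwise
    identical outputs.
    """
    design = design or default_design()
    signals = list(default_signals() if signals is None else signals)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    names = [s.name for s in signals]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate signal names")
    claimed_genes = sum(s.n_genes() for s in signals)
    if claimed_genes > n_genes:
        raise SizingError(
            f"signals claim {claimed_genes} genes but n_genes={n_genes}"
        )
    claimed_mets = sum(len(s.metabolite_ids) for s in signals)
    if claimed_mets > n_metabolites:
        raise SizingError(
            f"signals claim {claimed_mets} metabolites but n_metabolites={n_metabolites}"
        )
    cluster_ids = [c for s in signals for c in s.gene_clusters]
    if len(set(cluster_ids)) != len(cluster_ids):
        raise ValidationError("duplicate planted cluster ids across signals")
    met_ids_claimed = [m for s in signals for m in s.metabolite_ids]
    if len(set(met_ids_claimed)) != len(met_ids_claimed):
        raise ValidationError("duplicate metabolite ids across signals")
    for s in signals:
        if s.kind != "noise" and s.onset_day not in design.days and s.onset_day != 0:
            raise ValidationError(
                f"signal '{s.name}' onset_day {s.onset_day} not a design day"
            )

    rng = np.random.default_rng(seed)
    meta, obs_index = _observation_keys(design)
    n_samples = len(meta)
    n_obs = max(obs_index.values()) + 1
    max_day = float(design.days[-1])

    # --- assign entities to signals -------------------------------------
    gene_ids: list[str] = [f"G{i:05d}" for i in range(n_genes)]
    gene_labels: dict[str, str] = {}
    gene_signal: list[PlantedSignal | None] = [None] * n_genes
    cursor = 0
    cluster_signal: dict[str, str] = {}
    for s in signals:
        for cid, count in s.gene_clusters.items():
            cluster_signal[cid] = s.name
            for _ in range(count):
                gene_labels[gene_ids[cursor]] = cid
                gene_signal[cursor] = s
                cursor += 1
    for i in range(cursor, n_genes):
        gene_labels[gene_ids[i]] = NOISE_LABEL

    met_ids: list[str] = []
    met_labels: dict[str, str] = {}
    met_signal: list[PlantedSignal | None] = []
    for s in signals:
        for m in s.metabolite_ids:
            met_ids.append(m)
            met_labels[m] = s.name
            met_signal.append(s)
    for i in range(len(met_ids), n_metabolites):
        mid = f"M{i:03d}"
        met_ids.append(mid)
        met_labels[mid] = NOISE_LABEL
        met_signal.append(None)

    # --- per-signal sample-level effect vectors -------------------------
    effect: dict[str, np.ndarray] = {}
    for s in signals:
        vec = np.empty(n_samples)
        for j, (t, d) in enumerate(zip(meta["treatment"], meta["day"])):
            mult = s.treatment_multipliers.get(t, 1.0)
            vec[j] = s.amplitude * s.curve(float(d), max_day) * mult
        effect[s.name] = vec

    obs_cols = np.array([obs_index[sid] for sid in meta["sample_id"]])

    def build_matrix(n_entities, entity_signal):
        base = rng.uniform(*baseline_log2_range, size=n_entities)
        noise = rng.normal(0.0, noise_sd, size=(n_entities, n_obs)) if noise_sd > 0 else np.zeros((n_entities, n_obs))
        log2 = base[:, None] + noise[:, obs_cols]
        for i, s in enumerate(entity_signal):
            if s is not None and s.kind != "noise":
                log2[i] += effect[s.name]
        return np.exp2(log2)

    expr_values = build_matrix(n_genes, gene_signal)
    met_values = build_matrix(n_metabolites, met_signal)

    sample_index = pd.Index(meta["sample_id"], name="sample_id")
    expression = OmicsBlock(
        "transcriptome",
        pd.DataFrame(expr_values.T, index=sample_index, columns=gene_ids),
    )
    metabolome = OmicsBlock(
        "metabolome",
        pd.DataFrame(met_values.T, index=sample_index, columns=met_ids),
    )

    # --- annotation: one distinct bin per planted cluster ---------------
    cluster_bins = {
        cid: f"{cluster_signal[cid]}.{cid}" for cid in cluster_signal
    }
    ann_rows = []
    background_bin = 0
    for g in gene_ids:
        label = gene_labels[g]
        if label == NOISE_LABEL:
            ann_rows.append((g, f"background.bin{background_bin % 12:02d}"))
            background_bin += 1
        else:
            ann_rows.append((g, cluster_bins[label]))
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "bin_path"])

    truth = GroundTruth(
        signals=signals,
        gene_labels=gene_labels,
        metabolite_labels=met_labels,
        cluster_signal=cluster_signal,
        cluster_bins=cluster_bins,
        noise_sd=noise_sd,
        seed=seed,
    )
    return expression, metabolome, meta, annotation, truth


def write_dataset(
    outdir: str | Path,
    expression: OmicsBlock,
    metabolome: OmicsBlock,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the generated dataset as plain TSV (+ JSON ground truth)."""
    from .data import write_annotation, write_block, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    write_block(expression, paths["expression"], index_label="gene_id")
    write_block(metabolome, paths["metabolites"], index_label="metabolite_id")
    write_metadata(meta, paths["metadata"])
    write_annotation(annotation, paths["annotation"])
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        truth.write(paths["ground_truth"])
    return paths
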