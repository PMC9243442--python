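"""Synthetic two-group multi-omics cohorts with planted ground truth.

Every input the pipeline consumes is emulated here so the full analysis is
testable without any external download: three expression layers (mRNA,
miRNA, lncRNA) for a case/control cohort, a beta-value methylation matrix, a
paired hippocampus/cortex reference cohort, and a miRNA target-prediction
table. The generator plants four kinds of signal, each recorded in a
:class:`GroundTruth` object:

* ordinary differentially expressed features (a +/- log2 fold-change shift
  in cases);
* ceRNA triads driven by a latent per-sample miRNA activity ``a``:
  miRNA = 8 + a + noise, mRNA = 8 - coupling*a + noise, lncRNA =
  8 - coupling*a + noise, with ``a`` shifted downward in cases — so cases
  show lncRNA up, miRNA down, mRNA up, and the pooled correlations carry the
  sponge sign pattern (miRNA–mRNA < 0, miRNA–lncRNA < 0, lncRNA–mRNA > 0);
* hypomethylated-upregulated genes (a negative beta shift plus a positive
  expression shift in cases);
* tissue-confounded decoys: features shifted in cases only because case
  tissue is hippocampus and control tissue is cortex; the same offset
  appears between the reference cohort's paired tissues, so the reference
  filter can remove them.

Background features are i.i.d. Normal(8, noise_sd) on the log2 scale;
methylation backgrounds sit at a per-gene baseline drawn from (0.2, 0.8)
with small Gaussian jitter, clipped to [0.01, 0.99]. All draws are
deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import (
    AUTOSOMES,
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSetCollection,
    SampleSheet,
    TargetPredictionTable,
)


class ConfigError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's reference conditions: 20 cases vs 20
    controls, 200 features per layer, 5 planted triads with coupling 0.8 and
    noise_sd 0.5, 20 planted DE features per expression layer, 18
    tissue-confounded decoys, 2 hypomethylated-upregulated genes. A
    ``pilot_scale()`` preset with 6 cases vs 9 controls is provided for
    demonstration only.
    """

    n_case: int = 20
    n_control: int = 20
    n_mrna: int = 200
    n_mirna: int = 200
    n_lncrna: int = 200
    n_cpg_genes: int = 200
    n_planted_de: int = 20          # per expression layer
    n_planted_triads: int = 5
    n_planted_hypo_up: int = 2
    n_confounded: int = 18          # split round-robin across the three layers
    de_log2fc: float = 1.5
    triad_coupling: float = 0.8
    noise_sd: float = 0.5
    beta_shift: float = -0.25
    beta_noise_sd: float = 0.05
    tissue_offset: float = 2.0      # hippocampus-vs-cortex offset of confounded features
    n_reference_pairs: int = 10
    activity_shift: float = 2.5     # case-vs-control shift of the latent miRNA activity
    activity_sd: float = 0.75       # per-sample spread of the latent activity
    seed: int = 0

    @classmethod
    def pilot_scale(cls, **overrides) -> "SimulationConfig":
        """6 cases vs 9 controls, for demonstration at the original cohort size."""
        return cls(n_case=6, n_control=9, **overrides)

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case, "n_control": self.n_control,
            "n_mrna": self.n_mrna, "n_mirna": self.n_mirna,
            "n_lncrna": self.n_lncrna, "n_cpg_genes": self.n_cpg_genes,
            "n_planted_de": self.n_planted_de,
            "n_planted_triads": self.n_planted_triads,
            "n_planted_hypo_up": self.n_planted_hypo_up,
            "n_confounded": self.n_confounded,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.noise_sd <= 0 or self.beta_noise_sd <= 0 or self.activity_sd <= 0:
            raise ConfigError("noise standard deviations must be > 0")
        if not (0 < self.triad_coupling <= 1):
            raise ConfigError("triad_coupling must lie in (0, 1]")
        if self.n_cpg_genes > self.n_mrna:
            raise ConfigError("n_cpg_genes cannot exceed n_mrna")
        conf = _split_confounded(self.n_confounded)
        need = {
            "mRNA": self.n_planted_de + self.n_planted_triads
                    + self.n_planted_hypo_up + conf["mRNA"],
            "miRNA": self.n_planted_de + self.n_planted_triads + conf["miRNA"],
            "lncRNA": self.n_planted_de + self.n_planted_triads + conf["lncRNA"],
        }
        sizes = {"mRNA": self.n_mrna, "miRNA": self.n_mirna, "lncRNA": self.n_lncrna}
        for layer, n in need.items():
            if n > sizes[layer]:
                raise ConfigError(
                    f"planted counts for {layer} ({n}) exceed layer size {sizes[layer]}")
        if self.n_planted_hypo_up > self.n_cpg_genes:
            raise ConfigError("n_planted_hypo_up cannot exceed n_cpg_genes")


@dataclass
class GroundTruth:
    """What was planted, keyed the way the recovery metrics consume it."""

    de_features: dict[str, dict[str, str]]          # layer -> id -> up/down
    triads: list[tuple[str, str, str]]              # (lncRNA, miRNA, mRNA)
    hypo_up_genes: list[str]
    confounded_features: dict[str, list[str]]       # layer -> ids

    def all_confounded(self) -> set[str]:
        return {f for ids in self.confounded_features.values() for f in ids}

    def to_json(self) -> str:
        d = asdict(self)
        d["triads"] = [list(t) for t in self.triads]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["triads"] = [tuple(t) for t in d["triads"]]
        return cls(**d)


@dataclass
class Cohort:
    """Bundle of all simulated inputs for one cohort."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    methylation: ExpressionMatrix
    samples: SampleSheet
    annotation: FeatureAnnotation
    truth: GroundTruth

    def layer(self, name: str) -> ExpressionMatrix:
        return {"mRNA": self.mrna, "miRNA": self.mirna,
                "lncRNA": self.lncrna, "methylation": self.methylation}[name]


def _split_confounded(n: int) -> dict[str, int]:
    layers = ("mRNA", "miRNA", "lncRNA")
    return {layer: n // 3 + (1 if i < n % 3 else 0) for i, layer in enumerate(layers)}


@dataclass
class _Plan:
    ids: dict[str, list[str]]
    de: dict[str, dict[str, str]]
    triads: list[tuple[str, str, str]]
    hypo_up: list[str]
    confounded: dict[str, list[str]]
    chromosomes: dict[str, str]


def _plan(config: SimulationConfig) -> _Plan:
    """Deterministic role assignment shared by all generators of one config."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    ids = {
        "mRNA": [f"G{i:04d}" for i in range(config.n_mrna)],
        "miRNA": [f"miR-{i:04d}" for i in range(config.n_mirna)],
        "lncRNA": [f"lnc-{i:04d}" for i in range(config.n_lncrna)],
    }
    conf_split = _split_confounded(config.n_confounded)
    de: dict[str, dict[str, str]] = {}
    confounded: dict[str, list[str]] = {}
    triad_members: dict[str, list[str]] = {}
    hypo_up: list[str] = []
    for layer in ("mRNA", "miRNA", "lncRNA"):
        perm = list(rng.permutation(len(ids[layer])))
        take = lambda n: [ids[layer][perm.pop()] for _ in range(n)]
        triad_members[layer] = take(config.n_planted_triads)
        if layer == "mRNA":
            # hypomethylated-upregulated genes must carry a methylation profile
            hypo_up = []
            while len(hypo_up) < config.n_planted_hypo_up:
                idx = perm.pop()
                if idx < config.n_cpg_genes:
                    hypo_up.append(ids[layer][idx])
        de_ids = take(config.n_planted_de)
        directions = rng.choice(["up", "down"], size=len(de_ids))
        de[layer] = dict(zip(de_ids, directions))
        confounded[layer] = take(conf_split[layer])
    triads = list(zip(triad_members["lncRNA"], triad_members["miRNA"],
                      triad_members["mRNA"]))
    chromosomes = {}
    for layer in ("mRNA", "miRNA", "lncRNA"):
        for f in ids[layer]:
            chromosomes[f] = str(rng.choice(AUTOSOMES))
    return _Plan(ids, de, triads, hypo_up, confounded, chromosomes)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort (expression x3, methylation,
    sample sheet, annotation) plus its ground truth."""
    plan = _plan(config)
    rng = np.random.default_rng([config.seed, 202])
    n_case, n_ctrl = config.n_case, config.n_control
    n_samples = n_case + n_ctrl
    case_ids = [f"case_{i + 1:02d}" for i in range(n_case)]
    ctrl_ids = [f"control_{i + 1:02d}" for i in range(n_ctrl)]
    sample_ids = case_ids + ctrl_ids
    is_case = np.array([1.0] * n_case + [0.0] * n_ctrl)

    matrices: dict[str, pd.DataFrame] = {}
    for layer in ("mRNA", "miRNA", "lncRNA"):
        ids = plan.ids[layer]
        X = rng.normal(8.0, config.noise_sd, size=(len(ids), n_samples))
        row = {f: i for i, f in enumerate(ids)}
        for f, direction in plan.de[layer].items():
            sign = 1.0 if direction == "up" else -1.0
            X[row[f]] += sign * config.de_log2fc * is_case
        for f in plan.confounded[layer]:
            X[row[f]] += config.tissue_offset * is_case
        matrices[layer] = pd.DataFrame(X, index=ids, columns=sample_ids)

    # latent-activity triads: one independent activity per triad, lower in cases
    half = config.activity_shift / 2.0
    for lnc, mir, gene in plan.triads:
        a = rng.normal(0.0, config.activity_sd, size=n_samples)
        a += np.where(is_case == 1.0, -half, half)
        noise = lambda: rng.normal(0.0, config.noise_sd, size=n_samples)
        matrices["miRNA"].loc[mir] = 8.0 + a + noise()
        matrices["mRNA"].loc[gene] = 8.0 - config.triad_coupling * a + noise()
        matrices["lncRNA"].loc[lnc] = 8.0 - config.triad_coupling * a + noise()

    for gene in plan.hypo_up:
        matrices["mRNA"].loc[gene] = (
            rng.normal(8.0, config.noise_sd, size=n_samples)
            + config.de_log2fc * is_case
        )

    meth_ids = plan.ids["mRNA"][: config.n_cpg_genes]
    baselines = rng.uniform(0.2, 0.8, size=len(meth_ids))
    beta = baselines[:, None] + rng.normal(0.0, config.beta_noise_sd,
                                           size=(len(meth_ids), n_samples))
    meth_row = {f: i for i, f in enumerate(meth_ids)}
    for gene in plan.hypo_up:
        i = meth_row[gene]
        # keep the shifted betas away from the clip boundary
        base = rng.uniform(0.45, 0.8)
        beta[i] = base + rng.normal(0.0, config.beta_noise_sd, size=n_samples)
        beta[i] += config.beta_shift * is_case
    beta = np.clip(beta, 0.01, 0.99)

    samples = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "group": ["case"] * n_case + ["control"] * n_ctrl,
        "pair_id": [None] * n_samples,
    }))
    ann_rows = []
    for layer in ("mRNA", "miRNA", "lncRNA"):
        for f in plan.ids[layer]:
            ann_rows.append((f, plan.chromosomes[f], layer))
    annotation = FeatureAnnotation(pd.DataFrame(
        ann_rows, columns=["feature_id", "chromosome", "layer"]))
    truth = GroundTruth(
        de_features={layer: dict(plan.de[layer]) for layer in plan.de},
        triads=list(plan.triads),
        hypo_up_genes=list(plan.hypo_up),
        confounded_features={k: list(v) for k, v in plan.confounded.items()},
    )
    return Cohort(
        mrna=ExpressionMatrix(matrices["mRNA"], "mRNA"),
        mirna=ExpressionMatrix(matrices["miRNA"], "miRNA"),
        lncrna=ExpressionMatrix(matrices["lncRNA"], "lncRNA"),
        methylation=ExpressionMatrix(
            pd.DataFrame(beta, index=meth_ids, columns=sample_ids), "methylation"),
        samples=samples,
        annotation=annotation,
        truth=truth,
    )


def simulate_reference_pairs(config: SimulationConfig
                             ) -> tuple[ExpressionMatrix, SampleSheet]:
    """Paired hippocampus/cortex reference cohort over all cohort features.

    Confounded features carry a consistent ``tissue_offset`` between the two
    tissues of every pair; every other feature has zero expected paired
    difference.
    """
    if config.n_reference_pairs < 3:
        raise ConfigError("paired reference needs at least 3 pairs")
    plan = _plan(config)
    rng = np.random.default_rng([config.seed, 303])
    features = plan.ids["mRNA"] + plan.ids["miRNA"] + plan.ids["lncRNA"]
    confounded = {f for ids in plan.confounded.values() for f in ids}
    n_pairs = config.n_reference_pairs
    hip_ids = [f"ref_hip_{i + 1:02d}" for i in range(n_pairs)]
    ctx_ids = [f"ref_ctx_{i + 1:02d}" for i in range(n_pairs)]
    X = rng.normal(8.0, config.noise_sd, size=(len(features), 2 * n_pairs))
    for i, f in enumerate(features):
        if f in confounded:
            X[i, :n_pairs] += config.tissue_offset
    values = pd.DataFrame(X, index=features, columns=hip_ids + ctx_ids)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": hip_ids + ctx_ids,
        "group": ["case"] * n_pairs + ["control"] * n_pairs,
        "pair_id": [f"pair_{i + 1:02d}" for i in range(n_pairs)] * 2,
    }))
    return ExpressionMatrix(values, "mRNA"), sheet


def simulate_target_database(truth: GroundTruth, config: SimulationConfig,
                             decoy_fraction: float = 0.3,
                             seed: int | None = None) -> TargetPredictionTable:
    """Prediction table containing every planted sponge edge plus decoys.

    Decoys are drawn uniformly without replacement from all non-planted
    (miRNA, target) pairs at ``decoy_fraction`` of the candidate pool, and
    are deterministic under the seed (defaults to the config seed).
    """
    if not (0 <= decoy_fraction <= 1):
        raise ConfigError("decoy_fraction must lie in [0, 1]")
    plan = _plan(config)
    rng = np.random.default_rng([config.seed if seed is None else seed, 404])
    planted: list[tuple[str, str, str]] = []
    for lnc, mir, gene in truth.triads:
        planted.append((mir, gene, "mRNA"))
        planted.append((mir, lnc, "lncRNA"))
    planted_keys = {(m, t) for m, t, _ in planted}
    candidates: list[tuple[str, str, str]] = []
    for mir in plan.ids["miRNA"]:
        for layer in ("mRNA", "lncRNA"):
            for t in plan.ids[layer]:
                if (mir, t) not in planted_keys:
                    candidates.append((mir, t, layer))
    n_decoys = int(round(decoy_fraction * len(candidates)))
    pick = rng.choice(len(candidates), size=n_decoys, replace=False)
    rows = list(planted) + [candidates[i] for i in sorted(pick)]
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_layer"])
    df["n_sources"] = np.where(df.index < len(planted), 3,
                               rng.integers(1, 4, size=len(df)))
    return TargetPredictionTable(df)


def simulate_gene_sets(truth: GroundTruth, config: SimulationConfig,
                       n_decoy_sets: int = 8, set_size: int = 10,
                       seed: int | None = None) -> GeneSetCollection:
    """Small GMT-style collection with planted-truth sets plus random decoys.

    ``triad_targets`` holds the mRNAs of the planted triads (present only
    when at least two were planted), ``planted_de_up`` / ``planted_de_down``
    the planted differentially expressed mRNAs by direction; decoy sets are
    uniform draws from the background mRNAs.
    """
    plan = _plan(config)
    rng = np.random.default_rng([config.seed if seed is None else seed, 505])
    sets: dict[str, tuple[str, list[str]]] = {}
    triad_mrnas = [g for _, _, g in truth.triads]
    if len(triad_mrnas) >= 2:
        sets["triad_targets"] = ("mRNAs of planted sponge triads", triad_mrnas)
    up = [g for g, d in truth.de_features.get("mRNA", {}).items() if d == "up"]
    down = [g for g, d in truth.de_features.get("mRNA", {}).items() if d == "down"]
    if len(up) >= 2:
        sets["planted_de_up"] = ("planted upregulated mRNAs", up)
    if len(down) >= 2:
        sets["planted_de_down"] = ("planted downregulated mRNAs", down)
    special = set(triad_mrnas) | set(up) | set(down) | set(truth.hypo_up_genes)
    background = [g for g in plan.ids["mRNA"] if g not in special]
    for i in range(n_decoy_sets):
        k = min(set_size, len(background))
        if k < 2:
            break
        pick = rng.choice(len(background), size=k, replace=False)
        sets[f"decoy_set_{i + 1:02d}"] = (
            "random background mRNAs", [background[j] for j in sorted(pick)])
    return GeneSetCollection(sets)
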