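"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of the real inputs — an
interaction-evidence table whose scores straddle the prediction-filter
thresholds, log-scale two-group microarray matrices with planted uniform-
and subgroup-shift differential features, a TF gene list, and a clinical
table with scored tissue dots, a designated associated variable and
survival times — while planting a known set of biomarker-like miRNAs:

* each planted miRNA regulates a private module of exclusive target genes
  (genes no other miRNA touches) and its whole regulon is enriched for
  transcription factors, so its NOD and TFP stand out against the
  degree-preserving rewiring null;
* planted miRNAs and the genes of their modules are differentially
  expressed, so the condition-specific networks retain them.

Everything is driven by one integer seed; identical configurations yield
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descreen import CONTROL, DISEASE, ExpressionStudy
from .netbuild import EvidenceClass, Source

__all__ = ["SynthConfig", "GroundTruth", "generate_network_evidence",
           "generate_expression", "generate_clinical", "write_all"]


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic study.

    Network: ``n_mirnas`` miRNAs over a gene universe split into the
    planted miRNAs' exclusive modules (``n_planted`` ×
    ``planted_exclusive_targets`` genes) and a background pool; background
    edges are sampled at ``background_edge_density`` over miRNA ×
    background-pool pairs. ``n_tfs`` background-pool genes are TFs
    (background TF rate n_tfs / pool size ≈ 0.1); planted miRNAs pick TF
    targets at ``planted_tf_fraction`` throughout their regulon.

    Expression: Gaussian log-intensities, per-feature baseline, noise SD
    ``noise_sd``. Planted DE miRNAs shift uniformly by ``de_shift`` in all
    disease samples; planted DE genes shift by ``de_shift`` in a
    ``subgroup_fraction`` of disease samples (the cancer-outlier regime).
    """

    seed: int = 0
    n_mirnas: int = 300
    n_genes: int = 3000
    n_tfs: int = 250
    background_edge_density: float = 0.01
    n_planted: int = 20
    planted_exclusive_targets: int = 25
    planted_tf_fraction: float = 0.4
    n_background_de_mirnas: int = 100
    n_background_de_genes: int = 600
    n_samples_per_group: int = 20
    n_mrna_studies: int = 2
    de_shift: float = 1.5
    subgroup_fraction: float = 0.25
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    clinical_n: int = 90
    clinical_effect: float = 3.0
    survival_hazards: tuple[float, float] = (0.1, 0.3)
    censor_horizon: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.background_edge_density < 1:
            raise ValueError("background_edge_density must be in (0, 1)")
        if not 0 < self.subgroup_fraction <= 1:
            raise ValueError("subgroup_fraction must be in (0, 1]")
        if not 0 <= self.planted_tf_fraction <= 1:
            raise ValueError("planted_tf_fraction must be in [0, 1]")
        if self.n_planted > self.n_mirnas:
            raise ValueError("n_planted exceeds n_mirnas")
        if self.n_exclusive_genes + self.n_background_de_genes > self.n_genes:
            raise ValueError("requested exclusive targets exceed available genes")

    @property
    def n_exclusive_genes(self) -> int:
        return self.n_planted * self.planted_exclusive_targets

    @property
    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-{i + 1:04d}" for i in range(self.n_mirnas)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_mirnas: list[str]
    planted_de_mirnas: list[str]
    de_mirna_directions: dict[str, str]
    planted_de_genes: list[str]
    exclusive_targets: dict[str, list[str]]
    tf_genes: list[str]
    edges: list[tuple[str, str]]
    clinical_variable: str
    clinical_effect: float

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["edges"] = [list(e) for e in self.edges]
        Path(path).write_text(json.dumps(data, indent=0, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["edges"] = [tuple(e) for e in data["edges"]]
        return cls(**data)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# network + evidence


def generate_network_evidence(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Evidence table (netbuild input format) plus the planted truth.

    Every true edge carries evidence that survives the default prediction
    filters (a validated low-throughput record, or predictions from at
    least two tools with passing scores); decoy records — single-tool
    predictions, sub-threshold scores, high-throughput-only validations —
    are added so the filters have something to reject.
    """
    rng = _rng(config, 1)
    mirnas = config.mirna_ids
    genes = config.gene_ids
    planted = mirnas[: config.n_planted]
    exclusive_block = genes[: config.n_exclusive_genes]
    background_pool = genes[config.n_exclusive_genes:]

    tf_background = list(
        rng.choice(background_pool, size=config.n_tfs, replace=False)
    )
    tf_set = set(tf_background)

    exclusive_targets: dict[str, list[str]] = {}
    edges: list[tuple[str, str]] = []
    k = config.planted_exclusive_targets
    n_tf_excl = round(config.planted_tf_fraction * k)
    for i, m in enumerate(planted):
        module = exclusive_block[i * k: (i + 1) * k]
        exclusive_targets[m] = list(module)
        tf_set.update(module[:n_tf_excl])
        edges.extend((m, g) for g in module)

    # Background edges over miRNA × background-pool pairs. Planted miRNAs
    # preferentially hit TF genes at planted_tf_fraction (their regulon is
    # TF-rich as a whole); other miRNAs sample the pool uniformly, giving
    # the background TF rate.
    bg_tf = [g for g in background_pool if g in tf_set]
    bg_non_tf = [g for g in background_pool if g not in tf_set]
    n_bg_targets = int(round(config.background_edge_density * len(background_pool)))
    for m in mirnas:
        if m in exclusive_targets:
            n_tf_t = rng.binomial(n_bg_targets, config.planted_tf_fraction)
            chosen = list(rng.choice(bg_tf, size=min(n_tf_t, len(bg_tf)), replace=False))
            chosen += list(
                rng.choice(bg_non_tf, size=n_bg_targets - len(chosen), replace=False)
            )
        else:
            chosen = list(
                rng.choice(background_pool, size=n_bg_targets, replace=False)
            )
        edges.extend((m, g) for g in chosen)
    edges = sorted(set(edges))

    rows: list[dict] = []
    validated_sources = [s.value for s in
                         (Source.MIRTARBASE, Source.TARBASE, Source.MIRECORDS,
                          Source.MIR2DISEASE)]
    prediction_sources = [Source.HOCTAR.value, Source.EXPRTARGET.value,
                          Source.STARBASE.value]

    def pred_row(m: str, g: str, tool: str, passing: bool) -> dict:
        row = {"mirna": m, "gene": g, "source": tool,
               "evidence_class": EvidenceClass.PREDICTED.value,
               "hoctar_score": "", "exprtarget_score": "",
               "starbase_readnum": "", "starbase_bc": ""}
        if tool == Source.HOCTAR.value:
            lo, hi = (5.0, 10.0) if passing else (0.0, 5.0)
            row["hoctar_score"] = f"{rng.uniform(lo, hi):.4f}"
        elif tool == Source.EXPRTARGET.value:
            lo, hi = (1.5, 5.0) if passing else (0.0, 0.9)
            row["exprtarget_score"] = f"{rng.uniform(lo, hi):.4f}"
        else:
            if passing:
                row["starbase_readnum"] = str(int(rng.integers(10, 100)))
                row["starbase_bc"] = str(int(rng.integers(2, 10)))
            else:
                row["starbase_readnum"] = str(int(rng.integers(0, 10)))
                row["starbase_bc"] = str(int(rng.integers(0, 2)))
        return row

    n_hoctar_passing = 0
    for m, g in edges:
        if rng.random() < 0.3:  # validated low-throughput
            rows.append({"mirna": m, "gene": g,
                         "source": str(rng.choice(validated_sources)),
                         "evidence_class":
                             EvidenceClass.VALIDATED_LOW_THROUGHPUT.value,
                         "hoctar_score": "", "exprtarget_score": "",
                         "starbase_readnum": "", "starbase_bc": ""})
        else:  # agreed predictions from ≥2 tools
            n_tools = 2 if rng.random() < 0.7 else 3
            tools = list(rng.choice(prediction_sources, size=n_tools, replace=False))
            for tool in tools:
                rows.append(pred_row(m, g, tool, passing=True))
                if tool == Source.HOCTAR.value:
                    n_hoctar_passing += 1

    # decoys: pairs outside the true network whose evidence fails a filter
    n_decoys = max(len(edges) // 2, n_hoctar_passing)
    edge_set = set(edges)
    decoy_pairs: set[tuple[str, str]] = set()
    n_hoctar_decoys = 0
    made = 0
    while made < n_decoys:
        m = mirnas[int(rng.integers(0, len(mirnas)))]
        g = background_pool[int(rng.integers(0, len(background_pool)))]
        if (m, g) in edge_set or (m, g) in decoy_pairs:
            continue
        decoy_pairs.add((m, g))
        made += 1
        kind = rng.random()
        if n_hoctar_decoys < n_hoctar_passing:
            # low-scored HOCTAR records keep every passing edge in the top half
            rows.append(pred_row(m, g, Source.HOCTAR.value, passing=False))
            n_hoctar_decoys += 1
        elif kind < 0.4:  # single-tool passing prediction: agreement 1 < 2
            rows.append(pred_row(m, g, Source.EXPRTARGET.value, passing=True))
        elif kind < 0.7:  # sub-threshold scores
            rows.append(pred_row(m, g, Source.STARBASE.value, passing=False))
        else:  # high-throughput-only validation
            rows.append({"mirna": m, "gene": g,
                         "source": str(rng.choice(validated_sources)),
                         "evidence_class":
                             EvidenceClass.VALIDATED_HIGH_THROUGHPUT.value,
                         "hoctar_score": "", "exprtarget_score": "",
                         "starbase_readnum": "", "starbase_bc": ""})

    evidence = pd.DataFrame(rows, columns=["mirna", "gene", "source",
                                           "evidence_class", "hoctar_score",
                                           "exprtarget_score",
                                           "starbase_readnum", "starbase_bc"])
    evidence = evidence.sort_values(["mirna", "gene", "source"],
                                    kind="mergesort").reset_index(drop=True)

    de_bg = list(rng.choice(
        [m for m in mirnas if m not in exclusive_targets],
        size=config.n_background_de_mirnas, replace=False))
    de_mirnas = planted + sorted(de_bg)
    directions = {m: ("up" if rng.random() < 0.5 else "down") for m in de_mirnas}

    de_bg_genes = sorted(rng.choice(background_pool,
                                    size=config.n_background_de_genes,
                                    replace=False))
    de_genes = exclusive_block + list(de_bg_genes)

    truth = GroundTruth(
        planted_mirnas=list(planted),
        planted_de_mirnas=list(de_mirnas),
        de_mirna_directions=directions,
        planted_de_genes=list(de_genes),
        exclusive_targets=exclusive_targets,
        tf_genes=sorted(tf_set),
        edges=edges,
        clinical_variable="tumor_size_large",
        clinical_effect=config.clinical_effect,
    )
    return evidence, truth


# ---------------------------------------------------------------------------
# expression


def _study(values: np.ndarray, feature_ids: list[str], n_per_group: int,
           prefix: str) -> ExpressionStudy:
    samples = ([f"{prefix}_D{i + 1:03d}" for i in range(n_per_group)]
               + [f"{prefix}_C{i + 1:03d}" for i in range(n_per_group)])
    groups = pd.Series([DISEASE] * n_per_group + [CONTROL] * n_per_group,
                       index=samples)
    return ExpressionStudy(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        sample_groups=groups,
    )


def generate_expression(
    config: SynthConfig, truth: GroundTruth
) -> tuple[ExpressionStudy, list[ExpressionStudy]]:
    """(miRNA study, list of mRNA studies) with the planted DE structure.

    DE miRNAs shift uniformly in all disease samples (t-test regime); DE
    genes shift in only a ``subgroup_fraction`` of disease samples
    (outlier regime), with a per-gene random direction. Missing values are
    injected at ``missing_rate`` into the mRNA matrices.
    """
    rng = _rng(config, 2)
    n = config.n_samples_per_group

    # miRNA study: uniform shifts
    baseline = rng.normal(7.0, 1.0, size=config.n_mirnas)
    values = rng.normal(0.0, config.noise_sd,
                        size=(config.n_mirnas, 2 * n)) + baseline[:, None]
    idx = {m: i for i, m in enumerate(config.mirna_ids)}
    for m in truth.planted_de_mirnas:
        sign = 1.0 if truth.de_mirna_directions[m] == "up" else -1.0
        values[idx[m], :n] += sign * config.de_shift
    mirna_study = _study(values, config.mirna_ids, n, "mir")

    # mRNA studies: subgroup shifts, shared truth, independent noise
    n_sub = max(1, math.ceil(config.subgroup_fraction * n))
    gidx = {g: i for i, g in enumerate(config.gene_ids)}
    gene_sign = {g: (1.0 if rng.random() < 0.5 else -1.0)
                 for g in truth.planted_de_genes}
    mrna_studies = []
    for s in range(config.n_mrna_studies):
        srng = _rng(config, 10 + s)
        baseline_g = srng.normal(8.0, 1.5, size=config.n_genes)
        vals = srng.normal(0.0, config.noise_sd,
                           size=(config.n_genes, 2 * n)) + baseline_g[:, None]
        for g in truth.planted_de_genes:
            hit = srng.choice(n, size=n_sub, replace=False)
            vals[gidx[g], hit] += gene_sign[g] * config.de_shift
        if config.missing_rate > 0:
            mask = srng.random(vals.shape) < config.missing_rate
            # never blank out a whole feature
            full = mask.all(axis=1)
            mask[full, 0] = False
            vals = np.where(mask, np.nan, vals)
        mrna_studies.append(_study(vals, config.gene_ids, n, f"mrna{s + 1}"))
    return mirna_study, mrna_studies


# ---------------------------------------------------------------------------
# clinical


_PERCENT_MIDPOINTS = {0: 2.0, 1: 15.0, 2: 37.0, 3: 62.0, 4: 85.0}


def generate_clinical(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Clinical/TMA table: scored tumor dots, covariates, survival.

    The high/low expression split (weighted score ≥ 4) is associated with
    the designated binary variable at odds ratio ``clinical_effect``
    (effect 1 means independence); survival is exponential with
    group-specific hazards (high, low) censored uniformly up to the
    horizon.
    """
    rng = _rng(config, 3)
    p_high = 1 / 3
    base_odds = 1.5  # P(variable | low expression) = 0.6
    rows = []
    for i in range(config.clinical_n):
        high = rng.random() < p_high
        odds = base_odds / config.clinical_effect if high else base_odds
        var = rng.random() < odds / (1 + odds)
        score = int(rng.integers(4, 8)) if high else int(rng.integers(0, 4))
        intensity = int(rng.integers(max(0, score - 4), min(3, score) + 1))
        percent_score = score - intensity
        hazard = config.survival_hazards[0] if high else config.survival_hazards[1]
        t_event = rng.exponential(1 / hazard)
        t_censor = rng.uniform(0, config.censor_horizon)
        time = min(t_event, t_censor, config.censor_horizon)
        rows.append({
            "case_id": f"case{i + 1:03d}",
            "tissue": "tumor",
            "percent_positive": _PERCENT_MIDPOINTS[percent_score],
            "intensity": intensity,
            truth.clinical_variable: int(var),
            "time": round(max(time, 1e-3), 4),
            "event": int(t_event <= min(t_censor, config.censor_horizon)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission


def write_all(config: SynthConfig, out_dir: str | Path) -> GroundTruth:
    """Emit every pipeline input into ``out_dir``; returns the truth.

    Files: evidence.tsv, mirna_expr.tsv + groups_mirna.tsv,
    mrna_expr<k>.tsv + groups_mrna<k>.tsv, tf_list.txt, clinical.tsv,
    truth.json. Byte-identical for identical configurations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    evidence, truth = generate_network_evidence(config)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    mirna_study, mrna_studies = generate_expression(config, truth)

    def dump(study: ExpressionStudy, name: str, gname: str) -> None:
        study.values.round(6).to_csv(out / name, sep="\t",
                                     index_label="feature")
        study.sample_groups.to_csv(out / gname, sep="\t", header=False)

    dump(mirna_study, "mirna_expr.tsv", "groups_mirna.tsv")
    for i, study in enumerate(mrna_studies):
        dump(study, f"mrna_expr{i + 1}.tsv", f"groups_mrna{i + 1}.tsv")
    (out / "tf_list.txt").write_text("\n".join(truth.tf_genes) + "\n")
    generate_clinical(config, truth).to_csv(out / "clinical.tsv", sep="\t",
                                            index=False)
    truth.to_json(out / "truth.json")
    return truth
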