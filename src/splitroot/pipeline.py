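"""End-to-end orchestration: simulate -> preprocess -> DEG coding ->
inter-organ network -> set comparison -> enrichment, with a reproducibility
manifest.

Every stage draws randomness from a stream derived from the single top-level
seed and the stage's name, so toggling one stage never shifts another
stage's random numbers. The manifest records inputs, parameters, the seed,
and a SHA-256 content hash of every output file plus an overall ``run_hash``;
identical configuration and seed reproduce identical hashes byte for byte
(all numeric output is written with 9 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import network as net
from .matrix import ExpressionMatrix
from .preprocess import (
    dynamic_range_filter,
    filter_low_expression,
    full_quantile_normalize,
)
from .root import (
    interdependency_diagnostic,
    root_deg_pipeline,
    root_deg_set,
)
from .sets import (
    best_hit_reduce,
    flat_enrichment,
    map_gene_set,
    overlap_significance,
    three_way_overlap,
)
from .shoot import shoot_deg_pipeline, shoot_deg_set
from .simulate import (
    SimulationConfig,
    generate_multispecies_sets,
    generate_splitroot_experiment,
)

log = logging.getLogger("splitroot")

STAGES = (
    "simulate",
    "preprocess",
    "shoot_deg",
    "root_deg",
    "correlate",
    "network",
    "compare_sets",
    "enrich",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Parameters and stage toggles for a full run."""

    outdir: str = "splitroot_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulation: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # used when simulate is off
    shoot_fdr: float = 0.10
    tukey_alpha: float = 0.05
    root_pfp: float = 0.10
    n_perm: int = 1000
    corr_fdr: float = 0.001
    low_expr_log2: float = 5.0
    dynamic_range: float = 2.0
    log_offset: float = 1.0
    enrich_fdr: float = 0.05
    collapse_replicates: bool = False

    def __post_init__(self) -> None:
        for name, value in (
            ("shoot_fdr", self.shoot_fdr),
            ("tukey_alpha", self.tukey_alpha),
            ("root_pfp", self.root_pfp),
            ("corr_fdr", self.corr_fdr),
            ("enrich_fdr", self.enrich_fdr),
        ):
            if not (0 < value <= 1):
                raise PipelineError(f"{name} must lie in (0, 1]")
        stages = {s: True for s in STAGES}
        stages.update(self.stages)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        self.stages = stages

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        # stable stream per stage, independent of which stages are enabled
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to disk).

    A stage failure writes a ``.partial`` marker in the output directory and
    re-raises with the failing stage named; outputs of completed stages are
    retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    partial = out / ".partial"
    partial.write_text("run incomplete\n")
    outputs: list[Path] = []
    state: dict = {}
    try:
        for stage in STAGES:
            if not config.stages.get(stage, True):
                continue
            log.info("stage %s", stage)
            runner = globals()[f"_stage_{stage}"]
            outputs.extend(runner(config, out, state))
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(f"stage failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("stages", "outdir")
        },
        "stages": config.stages,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    manifest["run_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    partial.unlink()
    return manifest


# -- stages -----------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    sim = SimulationConfig(**{**config.simulation, "seed": config.stage_seed("simulate")})
    shoot, root, truth = generate_splitroot_experiment(sim)
    species_sets, homolog_map = generate_multispecies_sets(sim)
    truth.species_sets = species_sets
    state.update(shoot=shoot, root=root, truth=truth, homolog_map=homolog_map)

    paths = []

    def w(name, fn):
        p = out / name
        fn(p)
        paths.append(p)
        return p

    w("shoot_values.tsv", lambda p: sio.write_expression_matrix(shoot, p, out / "shoot_samples.tsv"))
    paths.append(out / "shoot_samples.tsv")
    w("root_values.tsv", lambda p: sio.write_expression_matrix(root, p, out / "root_samples.tsv"))
    paths.append(out / "root_samples.tsv")
    w("mobile_transcripts.txt", lambda p: sio.write_gene_list(truth.mobile_set, p))
    w("homolog_map.tsv", lambda p: sio.write_homolog_map(homolog_map, p))
    w("species_sets.gmt", lambda p: sio.write_gmt(species_sets, p))
    truth_df = pd.DataFrame(
        {
            "gene_id": sorted(truth.gene_class),
            "gene_class": [truth.gene_class[g] for g in sorted(truth.gene_class)],
        }
    )
    w("truth_gene_classes.tsv", lambda p: truth_df.to_csv(p, sep="\t", index=False))
    pairs_df = pd.DataFrame(
        truth.planted_pairs, columns=["shoot_gene", "root_gene", "condition", "sign"]
    )
    w("truth_planted_pairs.tsv", lambda p: pairs_df.to_csv(p, sep="\t", index=False))
    # flat annotation: one term per planted class plus random decoy terms
    rng = np.random.default_rng(config.stage_seed("simulate") + 1)
    ann_rows = []
    for cls in sorted(set(truth.gene_class.values())):
        for g in truth.genes_of_class(cls):
            ann_rows.append((f"class:{cls}", g))
    genes = sorted(truth.gene_class)
    for i in range(5):
        for g in rng.choice(genes, size=min(50, len(genes)), replace=False):
            ann_rows.append((f"random:{i}", g))
    ann_df = pd.DataFrame(ann_rows, columns=["term_id", "gene_id"])
    w("annotation.tsv", lambda p: ann_df.to_csv(p, sep="\t", index=False))
    return paths


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    if "shoot" in state:
        return
    needed = ["shoot_values", "shoot_samples", "root_values", "root_samples"]
    missing = [k for k in needed if k not in config.inputs]
    if missing:
        raise PipelineError(
            f"simulate disabled and inputs missing: {missing}"
        )
    state["shoot"] = sio.read_expression_matrix(
        config.inputs["shoot_values"], config.inputs["shoot_samples"]
    )
    state["root"] = sio.read_expression_matrix(
        config.inputs["root_values"], config.inputs["root_samples"]
    )
    if "mobile_list" in config.inputs:
        state["mobile_set"] = sio.read_gene_list(config.inputs["mobile_list"])
    if "homolog_map" in config.inputs:
        state["homolog_map"] = sio.read_homolog_map(config.inputs["homolog_map"])
    if "species_sets" in config.inputs:
        state["species_sets"] = sio.read_gmt(config.inputs["species_sets"])
    if "annotation" in config.inputs:
        state["annotation"] = sio.read_annotation(config.inputs["annotation"])


def _stage_preprocess(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(config, state)
    paths = []
    for organ in ("shoot", "root"):
        m = full_quantile_normalize(state[organ])
        state[f"{organ}_norm"] = m
        vp, sp = out / f"{organ}_normalized.tsv", out / f"{organ}_normalized_samples.tsv"
        sio.write_expression_matrix(m, vp, sp)
        paths += [vp, sp]
    return paths


def _normalized(state: dict, organ: str) -> ExpressionMatrix:
    return state.get(f"{organ}_norm", state[organ])


def _stage_shoot_deg(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(config, state)
    m = filter_low_expression(_normalized(state, "shoot"), config.low_expr_log2)
    log.info("shoot low-expression filter: %d -> %d genes",
             _normalized(state, "shoot").n_genes, m.n_genes)
    records = shoot_deg_pipeline(m, fdr_cutoff=config.shoot_fdr, alpha=config.tukey_alpha)
    state["shoot_records"] = records
    state["shoot_degs"] = shoot_deg_set(records)
    p = out / "shoot_deg.tsv"
    records.to_csv(p, sep="\t", index=False, float_format="%.9g")
    return [p]


def _stage_root_deg(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(config, state)
    m = filter_low_expression(_normalized(state, "root"), config.low_expr_log2)
    log.info("root low-expression filter: %d -> %d genes",
             _normalized(state, "root").n_genes, m.n_genes)
    records = root_deg_pipeline(
        m,
        pfp_cutoff=config.root_pfp,
        n_perm=config.n_perm,
        seed=config.stage_seed("root_deg"),
    )
    state["root_records"] = records
    state["root_degs"] = root_deg_set(records)
    paths = []
    p = out / "root_deg.tsv"
    records.to_csv(p, sep="\t", index=False, float_format="%.9g")
    paths.append(p)
    demand = set(records.loc[records["r1"] != 0, "gene_id"])
    supply = set(records.loc[records["r6"] != 0, "gene_id"])
    sio.write_gene_list(demand, out / "n_demand_genes.txt")
    sio.write_gene_list(supply, out / "n_supply_genes.txt")
    paths += [out / "n_demand_genes.txt", out / "n_supply_genes.txt"]
    stat, pval = interdependency_diagnostic(
        m, n_perm=min(config.n_perm, 500), seed=config.stage_seed("root_deg") + 1
    )
    diag = {
        "statistic_mean_paired_correlation": stat,
        "permutation_p": pval,
        "note": (
            "package-defined diagnostic of Sp.NO3/Sp.Cl half-to-half "
            "dependence; not a published test"
        ),
    }
    dp = out / "interdependency.json"
    dp.write_text(json.dumps(diag, indent=2, sort_keys=True) + "\n")
    paths.append(dp)
    return paths


def _stage_correlate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(config, state)
    mats = {}
    for organ in ("shoot", "root"):
        m = filter_low_expression(_normalized(state, organ), config.low_expr_log2)
        m = dynamic_range_filter(m, config.dynamic_range)
        log.info("%s correlation input: %d genes", organ, m.n_genes)
        mats[organ] = m
    pairs = net.interorgan_correlation(
        mats["shoot"],
        mats["root"],
        fdr_cutoff=config.corr_fdr,
        collapse_replicates=config.collapse_replicates,
    )
    state["pairs_raw"] = pairs
    p = out / "pairs_correlated.tsv"
    net.write_pairs(pairs, p)
    return [p]


def _stage_network(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    pairs = state.get("pairs_raw")
    if pairs is None:
        raise PipelineError("network stage needs the correlate stage")
    shoot_degs = state.get("shoot_degs", set())
    root_degs = state.get("root_degs", set())
    mobile = state["truth"].mobile_set if "truth" in state else state.get("mobile_set", set())
    step2 = net.filter_pairs_by_deg(pairs, shoot_degs, root_degs)
    log.info("DEG filter: %d -> %d pairs", len(pairs), len(step2))
    step3 = net.filter_pairs_by_mobility(step2, mobile)
    log.info("mobility filter: %d -> %d pairs", len(step2), len(step3))
    state["pairs_final"] = step3
    paths = []
    p = out / "pairs_final.tsv"
    net.write_pairs(step3, p)
    paths.append(p)
    venn = net.condition_venn(step3, split_by_sign=True)
    net.write_venn(venn, out / "pairs_venn.json")
    paths.append(out / "pairs_venn.json")
    g = net.build_network(step3)
    net.export_sif(g, out / "network.sif")
    net.export_graphml(g, out / "network.graphml")
    paths += [out / "network.sif", out / "network.graphml"]
    summary = {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
    (out / "network_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    paths.append(out / "network_summary.json")
    return paths


def _stage_compare_sets(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    species_sets = (
        state["truth"].species_sets if "truth" in state else state.get("species_sets")
    )
    homolog_map = state.get("homolog_map")
    if not species_sets or homolog_map is None:
        raise PipelineError("compare_sets needs species sets and a homolog map")
    mapping = best_hit_reduce(homolog_map)
    mapped = {sp: map_gene_set(genes, mapping) for sp, genes in species_sets.items()}
    universe = len(set(homolog_map["target_gene"]))
    names = list(mapped)
    result = {"universe": universe, "three_way": three_way_overlap(mapped)}
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = names[i], names[j]
            ov = overlap_significance(mapped[a], mapped[b], universe)
            result[f"{a}|{b}"] = {
                "size_a": ov.size_a,
                "size_b": ov.size_b,
                "overlap": ov.overlap,
                "p_upper": ov.p_upper,
                "fold_enrichment": ov.fold_enrichment,
            }
    p = out / "species_overlap.json"
    p.write_text(json.dumps(result, indent=2, sort_keys=True, default=float) + "\n")
    return [p]


def _stage_enrich(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    records = state.get("shoot_records")
    if records is None:
        raise PipelineError("enrich needs the shoot_deg stage")
    if "truth" in state:
        annotation = {
            f"class:{cls}": set(state["truth"].genes_of_class(cls))
            for cls in sorted(set(state["truth"].gene_class.values()))
        }
    else:
        annotation = state.get("annotation")
    if not annotation:
        raise PipelineError("enrich needs an annotation")
    universe = set(records["gene_id"])
    degs = state["shoot_degs"]
    result = flat_enrichment(degs, universe, annotation, fdr_cutoff=config.enrich_fdr)
    p = out / "shoot_deg_enrichment.tsv"
    result.to_csv(p, sep="\t", index=False, float_format="%.9g")
    return [p]
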