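"""Synthetic split-root experiment generator with planted ground truth.

The generator emulates the split-root nitrogen-foraging design: shoots
sampled under three conditions (C.NO3, Split, C.Cl) and roots under four
(C.NO3, Sp.NO3, Sp.Cl, C.Cl) at 0/2/4/8 h with three replicates. Genes are
planted in regulation classes with known condition offsets so that every
downstream stage — shoot Tukey coding, root rank-product coding, inter-organ
correlation, cross-species overlap — can be scored against truth.

Model
-----
Expression is log-normal around a deterministic log2 mean::

    log2 E[x_gs] = baseline_g + effect_log2fc * ramp(t_s) * offset(class_g, cond_s)
                   + pool_effect_{g, pool(s)}                 (split root halves)

with ``ramp(t) = min(t / 4 h, 1)`` — condition effects are absent at 0 h
(pre-treatment), half at 2 h and full from 4 h on, mirroring the sparse
2 h / rich 4-8 h differential-expression pattern of split-root time courses.
Multiplicative noise has coefficient of variation ``cv_noise``; ``noise``
class genes fluctuate with ``noise_cv_factor`` times that CV but carry no
condition effect, providing an expressed-but-null background. The two root
halves of one split plant share a plant-level random effect
(``pool_effect_sd``, log2 units), which makes the Sp.NO3/Sp.Cl
interdependency diagnostic detectable, as in real split-root data where both
halves are harvested from the same plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    ROOT_CONDITIONS,
    SHOOT_CONDITIONS,
    SHOOT_FOR_ROOT_CONDITION,
    make_sample_table,
)

RAMP_FULL_H = 4.0

GENE_CLASSES = (
    "split_induced",
    "split_repressed",
    "n_tracking",
    "depletion_induced",
    "constant",
    "noise",
)

#: planted per-condition offsets, in units of effect_log2fc
SHOOT_OFFSETS = {
    "split_induced": {"Split": 1.0},
    "split_repressed": {"Split": -1.0},
    "n_tracking": {"C.NO3": 1.0, "C.Cl": -1.0},
    "depletion_induced": {"C.Cl": 1.0},
    "constant": {},
    "noise": {},
}
ROOT_OFFSETS = {
    "split_induced": {"Sp.NO3": 1.0, "Sp.Cl": 1.0},
    "split_repressed": {"Sp.NO3": -1.0, "Sp.Cl": -1.0},
    "n_tracking": {"C.NO3": 1.0, "Sp.NO3": 1.0, "Sp.Cl": -1.0, "C.Cl": -1.0},
    "depletion_induced": {"Sp.Cl": 1.0, "C.Cl": 1.0},
    "constant": {},
    "noise": {},
}

#: Tukey code (T1, T2, T3) implied by the planted shoot offsets
PLANTED_SHOOT_CODE = {
    "split_induced": (0, 1, 1),
    "split_repressed": (0, -1, -1),
    "n_tracking": (1, 1, -1),
    "depletion_induced": (-1, -1, 0),
    "constant": (0, 0, 0),
    "noise": (0, 0, 0),
}
#: RP code (R1..R6) implied by the planted root offsets; digit +1 means the
#: first condition of the contrast is the LOWER one
PLANTED_ROOT_CODE = {
    "split_induced": (1, 1, 0, 0, -1, -1),
    "split_repressed": (-1, -1, 0, 0, 1, 1),
    "n_tracking": (0, -1, -1, -1, -1, 0),
    "depletion_induced": (0, 1, 1, 1, 1, 0),
    "constant": (0, 0, 0, 0, 0, 0),
    "noise": (0, 0, 0, 0, 0, 0),
}


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_class_counts(n_genes: int) -> dict[str, int]:
    # roughly the DEG fraction of real split-root shoot data at 4-8 h
    # (~20-25% of expressed genes): 5% per regulation class, 20% expressed
    # null "noise" genes, the remainder flat
    frac = {
        "split_induced": 0.05,
        "split_repressed": 0.05,
        "n_tracking": 0.05,
        "depletion_induced": 0.05,
        "noise": 0.20,
    }
    counts = {k: int(round(v * n_genes)) for k, v in frac.items()}
    counts["constant"] = n_genes - sum(counts.values())
    return counts


@dataclass
class SimulationConfig:
    """Parameters of the synthetic split-root experiment."""

    n_genes: int = 2000
    n_replicates: int = 3
    time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    class_counts: dict[str, int] | None = None
    effect_log2fc: float = 2.0
    cv_noise: float = 0.1
    noise_cv_factor: float = 3.0
    n_planted_pairs: int = 0
    pair_r_target: float = 0.95
    mobile_fraction: float = 0.1
    pool_effect_sd: float = 0.15
    species_set_sizes: dict[str, int] = field(
        default_factory=lambda: {"arabidopsis": 60, "tomato": 50, "maize": 40}
    )
    species_shared: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("arabidopsis", "tomato"): 8,
            ("arabidopsis", "maize"): 5,
            ("tomato", "maize"): 4,
        }
    )
    species_triple_shared: int = 0
    species_universe: int = 500
    seed: int = 0

    def resolved_class_counts(self) -> dict[str, int]:
        counts = (
            dict(self.class_counts)
            if self.class_counts is not None
            else _default_class_counts(self.n_genes)
        )
        for name in counts:
            if name not in GENE_CLASSES:
                raise ConfigurationError(
                    f"unknown gene class {name!r}; allowed: {GENE_CLASSES}"
                )
        total = sum(counts.values())
        if total > self.n_genes:
            raise ConfigurationError(
                f"class_counts sum to {total} > n_genes = {self.n_genes}"
            )
        counts.setdefault("constant", 0)
        counts["constant"] += self.n_genes - total
        return counts

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_genes and n_replicates must be positive")
        t = np.asarray(self.time_points_h, dtype=float)
        if len(t) < 1 or (np.diff(t) <= 0).any() or (t < 0).any():
            raise ConfigurationError("time_points_h must be non-negative, strictly increasing")
        if self.cv_noise <= 0 or self.effect_log2fc <= 0:
            raise ConfigurationError("cv_noise and effect_log2fc must be positive")
        if not (0 < self.pair_r_target <= 1):
            raise ConfigurationError("pair_r_target must lie in (0, 1]")
        if not (0 <= self.mobile_fraction <= 1):
            raise ConfigurationError("mobile_fraction must lie in [0, 1]")
        if self.n_planted_pairs < 0:
            raise ConfigurationError("n_planted_pairs must be non-negative")
        self.resolved_class_counts()


@dataclass
class SyntheticTruth:
    """Planted structure of one synthetic experiment."""

    gene_class: dict[str, str]
    planted_shoot_code: dict[str, tuple[int, int, int]]
    planted_root_code: dict[str, tuple[int, ...]]
    planted_pairs: list[tuple[str, str, str, int]]
    mobile_set: set[str]
    species_sets: dict[str, set[str]]
    #: noise-free expected log2 profiles, genes x (condition, time) columns
    expected_shoot_log2: pd.DataFrame
    expected_root_log2: pd.DataFrame

    def genes_of_class(self, name: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == name]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # fixed stream indices keep sub-streams independent of one another and
    # of stage toggles
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _ramp(t: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(t, dtype=float) / RAMP_FULL_H, 1.0)


def _sample_records(organ: str, conditions, config: SimulationConfig) -> list[dict]:
    records = []
    for cond in conditions:
        for t in config.time_points_h:
            for rep in range(1, config.n_replicates + 1):
                if cond in ("Split", "Sp.NO3", "Sp.Cl"):
                    pool = f"split_t{t:g}_r{rep}"
                else:
                    pool = f"{cond}_t{t:g}_r{rep}"
                records.append(
                    {
                        "sample_id": f"{organ}_{cond}_t{t:g}_r{rep}",
                        "organ": organ,
                        "condition": cond,
                        "time_h": float(t),
                        "replicate": rep,
                        "plant_pool_id": pool,
                        "genotype": "Col-0",
                        "species": "arabidopsis",
                    }
                )
    return records


def _expected_log2(
    organ: str, conditions, config: SimulationConfig, classes: np.ndarray,
    baseline: np.ndarray,
) -> pd.DataFrame:
    offsets = SHOOT_OFFSETS if organ == "shoot" else ROOT_OFFSETS
    cols = pd.MultiIndex.from_product(
        [conditions, list(config.time_points_h)], names=["condition", "time_h"]
    )
    out = np.empty((len(classes), len(cols)))
    for j, (cond, t) in enumerate(cols):
        ramp = float(_ramp(np.array([t]))[0])
        off = np.array([offsets[c].get(cond, 0.0) for c in classes])
        out[:, j] = baseline + config.effect_log2fc * ramp * off
    genes = [f"G{i:05d}" for i in range(len(classes))]
    return pd.DataFrame(out, index=genes, columns=cols)


def generate_splitroot_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate shoot and root matrices plus the planted truth.

    Identical (config, seed) pairs produce bitwise-identical output. When
    ``config.n_planted_pairs > 0`` correlated shoot-root pairs are planted
    (see :func:`generate_planted_pairs`) before returning.
    """
    config.validate()
    counts = config.resolved_class_counts()
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    # classes assigned in declared order, then shuffled deterministically so
    # class membership is not confounded with baseline order
    flat = [name for name in GENE_CLASSES for _ in range(counts.get(name, 0))]
    perm = _rng(config, 0).permutation(config.n_genes)
    classes = np.array(flat, dtype=object)[perm]
    gene_class = dict(zip(genes, classes))

    baseline = _rng(config, 1).uniform(5.0, 15.0, size=config.n_genes)

    sigma = np.full(config.n_genes, np.sqrt(np.log1p(config.cv_noise**2)))
    noisy = classes == "noise"
    sigma[noisy] = np.sqrt(np.log1p((config.cv_noise * config.noise_cv_factor) ** 2))
    log2e = np.log2(np.e)

    matrices = {}
    expected = {}
    pool_rng = _rng(config, 2)
    pool_effect: dict[str, np.ndarray] = {}  # pool id -> per-gene log2 effect

    for stream, (organ, conditions) in enumerate(
        [("shoot", SHOOT_CONDITIONS), ("root", ROOT_CONDITIONS)], start=3
    ):
        records = _sample_records(organ, conditions, config)
        samples = make_sample_table(records)
        exp = _expected_log2(organ, conditions, config, classes, baseline)
        expected[organ] = exp
        mu = np.column_stack(
            [exp[(row["condition"], row["time_h"])] for _, row in samples.iterrows()]
        )
        if organ == "root":
            for j, (_, row) in enumerate(samples.iterrows()):
                if row["condition"] in ("Sp.NO3", "Sp.Cl"):
                    pool = row["plant_pool_id"]
                    if pool not in pool_effect:
                        pool_effect[pool] = pool_rng.normal(
                            0.0, config.pool_effect_sd, size=config.n_genes
                        )
                    mu[:, j] = mu[:, j] + pool_effect[pool]
        noise = _rng(config, stream).normal(size=mu.shape) * sigma[:, None]
        values = 2.0**mu * np.exp(noise)
        matrices[organ] = ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=samples.index),
            samples=samples,
            scale="linear",
        )

    mobile_rng = _rng(config, 6)
    n_mobile = int(round(config.mobile_fraction * config.n_genes))
    mobile = set(np.array(genes)[mobile_rng.choice(config.n_genes, n_mobile, replace=False)])

    truth = SyntheticTruth(
        gene_class=gene_class,
        planted_shoot_code={g: PLANTED_SHOOT_CODE[c] for g, c in gene_class.items()},
        planted_root_code={g: PLANTED_ROOT_CODE[c] for g, c in gene_class.items()},
        planted_pairs=[],
        mobile_set=mobile,
        species_sets={},
        expected_shoot_log2=expected["shoot"],
        expected_root_log2=expected["root"],
    )

    shoot, root = matrices["shoot"], matrices["root"]
    if config.n_planted_pairs > 0:
        shoot, root, _ = generate_planted_pairs(config, shoot, root, truth)
    return shoot, root, truth


def generate_planted_pairs(
    config: SimulationConfig,
    shoot: ExpressionMatrix,
    root: ExpressionMatrix,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[tuple[str, str, str, int]]]:
    """Plant inter-organ correlated gene pairs into the matrices.

    Each pair rewrites one root gene's profile under one root condition as a
    noisy affine transform (with the pair's sign) of its shoot partner's
    realized log2 profile, calibrated so the expected Pearson correlation
    over the matched time x replicate series is ``pair_r_target``. Shoot
    partners are drawn from planted regulation-class genes (so the pairs
    survive the differential-expression filter); root partners are drawn
    from ``constant`` genes, whose profiles are then overwritten.
    """
    if config.n_planted_pairs == 0:
        return shoot, root, []
    if truth is None:
        raise ConfigurationError("planting pairs requires the experiment truth")
    rng = _rng(config, 7)
    de_classes = ("split_induced", "split_repressed", "n_tracking", "depletion_induced")
    shoot_pool = [g for c in de_classes for g in truth.genes_of_class(c)]
    root_pool = truth.genes_of_class("constant")
    n = config.n_planted_pairs
    if n > len(shoot_pool) or n > len(root_pool):
        raise ConfigurationError(
            f"cannot plant {n} pairs: {len(shoot_pool)} eligible shoot genes, "
            f"{len(root_pool)} eligible root genes"
        )
    shoot_genes = [str(g) for g in np.array(shoot_pool)[rng.choice(len(shoot_pool), n, replace=False)]]
    root_genes = [str(g) for g in np.array(root_pool)[rng.choice(len(root_pool), n, replace=False)]]

    root_values = root.values.copy()
    pairs: list[tuple[str, str, str, int]] = []
    tau = np.sqrt(max(1.0 / config.pair_r_target**2 - 1.0, 0.0))
    for i, (sg, rg) in enumerate(zip(shoot_genes, root_genes)):
        cond = ROOT_CONDITIONS[i % len(ROOT_CONDITIONS)]
        sign = 1 if i % 2 == 0 else -1
        shoot_cond = SHOOT_FOR_ROOT_CONDITION[cond]
        s_cols = shoot.select(condition=shoot_cond).ordered(("time_h", "replicate"))
        r_cols = root.select(condition=cond).ordered(("time_h", "replicate"))
        x = np.log2(s_cols.values.loc[sg].to_numpy(dtype=float))
        xs = (x - x.mean()) / x.std()
        y = sign * xs + tau * rng.normal(size=x.size)
        base = float(np.log2(root.values.loc[rg]).mean())
        y_log2 = base + x.std() * y
        root_values.loc[rg, r_cols.samples.index] = 2.0**y_log2
        pairs.append((sg, rg, cond, sign))
        # the partner now tracks the shoot gene's planted profile under cond
        exp_s = truth.expected_shoot_log2.loc[sg, shoot_cond]
        for t, v in exp_s.items():
            truth.expected_root_log2.loc[rg, (cond, t)] = base + sign * (
                v - exp_s.mean()
            )
    truth.planted_pairs.extend(pairs)
    new_root = ExpressionMatrix(values=root_values, samples=root.samples, scale=root.scale)
    return shoot, new_root, pairs


def expected_profile_correlation(
    truth: SyntheticTruth,
    shoot_genes,
    root_genes,
    conditions,
) -> np.ndarray:
    """Correlation of noise-free expected profiles for shoot-root gene pairs.

    For each (shoot gene, root gene, root condition) triple, the Pearson
    correlation of the planted (noise-free) log2 mean profiles over the time
    course is returned, with the shoot side taken under the condition
    matched to the root condition. Pairs involving a flat expected profile
    get 0. This is the ground truth against which recovered correlated
    pairs are scored: the planted design makes these values essentially
    bimodal (near 0, or near +/-1 for genes sharing a condition ramp).
    """
    shoot_genes = np.asarray(shoot_genes)
    root_genes = np.asarray(root_genes)
    conditions = np.asarray(conditions)
    out = np.zeros(len(shoot_genes))
    for cond in np.unique(conditions):
        sel = conditions == cond
        X = truth.expected_shoot_log2[SHOOT_FOR_ROOT_CONDITION[cond]]
        Y = truth.expected_root_log2[cond]
        xs = X.sub(X.mean(axis=1), axis=0)
        ys = Y.sub(Y.mean(axis=1), axis=0)
        xn = np.sqrt((xs**2).sum(axis=1))
        yn = np.sqrt((ys**2).sum(axis=1))
        num = (
            xs.loc[shoot_genes[sel]].to_numpy()
            * ys.loc[root_genes[sel]].to_numpy()
        ).sum(axis=1)
        den = xn.loc[shoot_genes[sel]].to_numpy() * yn.loc[root_genes[sel]].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / den, 0.0)
        out[sel] = rho
    return out


def generate_multispecies_sets(
    config: SimulationConfig,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Generate per-species DEG sets and a many-to-one homolog map.

    The first species listed in ``species_set_sizes`` is the reference
    namespace (Arabidopsis-like ``AT#####`` ids). Other species use native
    ids mapped onto the reference by a scored homolog table containing, per
    source gene, one top-scoring true hit plus lower-scoring decoys; after
    best-hit reduction the pairwise intersections of the mapped sets equal
    the configured shared sizes exactly, and the three-way intersection
    equals ``species_triple_shared`` (empty by default).
    """
    config.validate()
    species = list(config.species_set_sizes)
    if len(species) != 3:
        raise ConfigurationError("exactly three species are required")
    sizes = config.species_set_sizes
    shared = {frozenset(k): v for k, v in config.species_shared.items()}
    for key in shared:
        if not key <= set(species):
            raise ConfigurationError(f"unknown species pair {sorted(key)}")
    t3 = config.species_triple_shared
    a, b, c = species
    ab = shared.get(frozenset((a, b)), 0) - t3
    ac = shared.get(frozenset((a, c)), 0) - t3
    bc = shared.get(frozenset((b, c)), 0) - t3
    if min(ab, ac, bc) < 0:
        raise ConfigurationError("pairwise shared sizes must be >= triple_shared")
    only = {
        a: sizes[a] - ab - ac - t3,
        b: sizes[b] - ab - bc - t3,
        c: sizes[c] - ac - bc - t3,
    }
    if min(only.values()) < 0:
        raise ConfigurationError("shared sizes exceed a species set size")
    n_ref = t3 + ab + ac + bc + sum(only.values())
    if n_ref > config.species_universe:
        raise ConfigurationError("species_universe smaller than the union of sets")

    ref = [f"AT{i:05d}" for i in range(config.species_universe)]
    blocks = iter(ref)

    def take(k):
        return [next(blocks) for _ in range(k)]

    block_t3 = take(t3)
    block_ab, block_ac, block_bc = take(ab), take(ac), take(bc)
    block_only = {s: take(only[s]) for s in species}
    ref_sets = {
        a: block_t3 + block_ab + block_ac + block_only[a],
        b: block_t3 + block_ab + block_bc + block_only[b],
        c: block_t3 + block_ac + block_bc + block_only[c],
    }

    prefix = {a: "AT", b: "SL", c: "ZM"}
    rng = _rng(config, 8)
    species_sets: dict[str, set[str]] = {}
    records = []
    counter = {s: 0 for s in species}
    for s in species:
        native = set()
        for target in ref_sets[s]:
            if s == a:
                source = target  # reference species: native namespace
            else:
                source = f"{prefix[s]}{counter[s]:05d}"
                counter[s] += 1
            native.add(source)
            top = 200.0 + rng.uniform(0, 100)
            records.append({"source_gene": source, "target_gene": target, "score": top})
            for _ in range(int(rng.integers(0, 3))):  # lower-scoring decoys
                decoy = ref[int(rng.integers(0, len(ref)))]
                if decoy != target:
                    records.append(
                        {
                            "source_gene": source,
                            "target_gene": decoy,
                            "score": top - rng.uniform(10, 100),
                        }
                    )
        species_sets[s] = native
    homolog_map = pd.DataFrame.from_records(
        records, columns=["source_gene", "target_gene", "score"]
    )
    return species_sets, homolog_map
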