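"""Synthetic tumour scRNA-seq generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: log-normal
baseline expression shared across cell populations; carcinoma clones carrying
large chromosomal copy-number segments that shift expression by an attenuated
log2(CN/2); population marker modules (T, B, macrophage, stromal, epithelial);
mean-dependent logistic dropout; TPM renormalisation; and fixed-copy RNA
spike-ins. Every cell's true population, clone and copy-number track is
returned for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import ExpressionMatrix, SegmentSet, sort_annotation

__all__ = [
    "SimulationConfig",
    "CloneCnv",
    "SyntheticTruth",
    "Experiment",
    "make_annotation",
    "chromosome_lengths",
    "simulate_clone_cnv",
    "clone_to_segments",
    "default_marker_sets",
    "signature_sets",
    "draw_baseline",
    "simulate_cells",
    "simulate_normal_reference",
    "simulate_experiment",
]

#: copy number 0 is mapped to this many copies before log2 so a homozygous
#: deletion still yields a finite simulated signal
ZERO_CN_COPIES = 0.1

SPIKE_PREFIX = "SPIKE"


class ConfigurationError(ValueError):
    pass


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; ``seed`` fixes all randomness.

    ``baseline_log_mean_sd`` parameterises the per-gene log2 baseline means;
    ``cnv_attenuation`` scales how much a DNA copy-number change propagates
    into expression (1 = full dosage effect); dropout is logistic in the
    per-gene mean with 50% loss at ``dropout_midpoint`` (log2 units);
    ``spikein_copies`` mirrors a three-spike external control series.
    """

    n_genes: int = 3000
    n_chromosomes: int = 6
    chromosome_length: int = 100_000_000
    cells_per_population: dict = field(default_factory=lambda: {
        "carcinoma": 300, "T": 60, "B": 45, "macrophage": 45, "stromal": 30,
    })
    baseline_log_mean_sd: tuple = (3.0, 1.5)
    cnv_attenuation: float = 0.8
    dropout_midpoint: float = 1.0
    dropout_slope: float = 1.0
    noise_sd: float = 1.0
    spikein_copies: tuple = (12_200, 912, 62)
    marker_effect: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ConfigurationError("n_genes, n_chromosomes, chromosome_length must be positive")
        if any(n <= 0 for n in self.cells_per_population.values()):
            raise ConfigurationError("cell counts must be positive")
        if not (0 <= self.cnv_attenuation <= 1):
            raise ConfigurationError("cnv_attenuation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


@dataclass
class CloneCnv:
    """True copy-number state of one carcinoma clone.

    ``segments`` are (chromosome, start, end, copy_number) with 0-based
    half-open coordinates; regions not covered by any segment are diploid.
    """

    clone_id: str
    segments: list

    def cn_track(self, annotation: pd.DataFrame) -> pd.Series:
        """Per-gene integer copy number; a gene takes the CN of the segment
        containing its (0-based) start position."""
        cn = pd.Series(2, index=annotation.index, dtype=int)
        pos = annotation["start"].astype(int) - 1
        for chrom, start, end, copy in self.segments:
            hit = (annotation["chromosome"] == chrom) & (pos >= start) & (pos < end)
            cn[hit] = copy
        return cn


@dataclass
class SyntheticTruth:
    """Ground truth for every simulated cell.

    ``cells`` is indexed by cell id with columns population, clone_id, group;
    ``clone_cn`` is genes x clones (integer copy number, diploid elsewhere).
    """

    cells: pd.DataFrame
    clone_cn: pd.DataFrame

    def cn_track(self, cell_id: str) -> pd.Series:
        clone = self.cells.at[cell_id, "clone_id"]
        if clone is None or (isinstance(clone, float) and np.isnan(clone)):
            return pd.Series(2, index=self.clone_cn.index, dtype=int)
        return self.clone_cn[clone]

    @property
    def populations(self) -> pd.Series:
        return self.cells["population"]


@dataclass
class Experiment:
    """Everything one synthetic study produces, bundled."""

    config: SimulationConfig
    annotation: pd.DataFrame
    clones: list
    marker_sets: dict
    matrix: ExpressionMatrix
    truth: SyntheticTruth
    normal: ExpressionMatrix
    baseline: pd.Series | None = None


def make_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced genes on equal-length chromosomes; deterministic.

    The remainder of ``n_genes / n_chromosomes`` is spread one gene at a time
    over the first chromosomes, so per-chromosome counts differ by at most 1.
    """
    base, rem = divmod(cfg.n_genes, cfg.n_chromosomes)
    rows = []
    g = 0
    for ci in range(cfg.n_chromosomes):
        count = base + (1 if ci < rem else 0)
        if count == 0:
            continue
        spacing = cfg.chromosome_length // (count + 1)
        gene_len = max(1, min(1000, spacing - 1))
        for j in range(count):
            start = (j + 1) * spacing
            rows.append((f"G{g:05d}", f"chr{ci + 1}", start, start + gene_len - 1))
            g += 1
    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"]).set_index("gene_id")
    return sort_annotation(ann)


def chromosome_lengths(annotation: pd.DataFrame, round_to: int | None = None) -> dict:
    """Chromosome lengths derived from the right-most annotated gene."""
    lengths = annotation.groupby("chromosome", sort=False)["end"].max().to_dict()
    if round_to:
        lengths = {c: int(np.ceil(v / round_to) * round_to) for c, v in lengths.items()}
    return lengths


def simulate_clone_cnv(
    annotation: pd.DataFrame,
    n_segments: int,
    seed: int,
    clone_id: str = "clone1",
    copy_numbers: tuple = (0, 1, 3, 4),
    min_frac: float = 0.25,
    max_frac: float = 0.5,
    chrom_lengths: dict | None = None,
) -> CloneCnv:
    """Draw ``n_segments`` non-overlapping aneuploid segments for one clone.

    Segment lengths are uniform fractions of the chromosome; copy numbers are
    drawn from ``copy_numbers`` (2 is the implicit background).
    """
    if n_segments < 0:
        raise ConfigurationError("n_segments must be >= 0")
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = chromosome_lengths(annotation)
    chroms = list(chrom_lengths)
    placed: list = []
    attempts = 0
    while len(placed) < n_segments:
        attempts += 1
        if attempts > 200 * max(1, n_segments):
            raise SimulationError(
                f"could not place {n_segments} non-overlapping segments after {attempts} attempts"
            )
        chrom = chroms[rng.integers(len(chroms))]
        L = chrom_lengths[chrom]
        seg_len = int(rng.uniform(min_frac, max_frac) * L)
        start = int(rng.uniform(0, L - seg_len))
        end = start + seg_len
        if any(c == chrom and start < e and s < end for c, s, e, _ in placed):
            continue
        copy = int(copy_numbers[rng.integers(len(copy_numbers))])
        placed.append((chrom, start, end, copy))
    return CloneCnv(clone_id=clone_id, segments=placed)


def clone_to_segments(clone: CloneCnv, min_length: int = 10_000) -> SegmentSet:
    """True CN segments as a WES-style SegmentSet with log2(CN/2) ratios."""
    rows = [
        (chrom, start, end, float(np.log2(max(copy, ZERO_CN_COPIES) / 2.0)))
        for chrom, start, end, copy in clone.segments
    ]
    return SegmentSet(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "log2_ratio"]),
        min_length=min_length,
    )


def default_marker_sets(
    annotation: pd.DataFrame,
    n_per_set: int = 40,
    populations: tuple = ("T", "B", "macrophage", "stromal", "carcinoma"),
) -> dict:
    """Disjoint marker gene modules, each scattered across the genome so marker
    expression never mimics a chromosomal copy-number footprint."""
    n_pops = len(populations)
    total = n_per_set * n_pops
    if total > len(annotation):
        raise ConfigurationError("not enough genes for the requested marker sets")
    idx = np.unique(np.linspace(0, len(annotation) - 1, total).astype(int))
    genes = annotation.index.to_numpy()[idx]
    return {pop: [str(g) for g in genes[i::n_pops]] for i, pop in enumerate(populations)}


def signature_sets(marker_sets: dict) -> dict:
    """Immune / stromal / epithelial scoring sets derived from the marker modules."""
    immune = []
    for pop in ("T", "B", "macrophage"):
        immune.extend(marker_sets.get(pop, []))
    return {
        "immune": immune,
        "stromal": list(marker_sets.get("stromal", [])),
        "epithelial": list(marker_sets.get("carcinoma", [])),
    }


def draw_baseline(annotation: pd.DataFrame, cfg: SimulationConfig, rng=None) -> pd.Series:
    """Per-gene baseline log2 mean expression, drawn once per experiment."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m, sd = cfg.baseline_log_mean_sd
    return pd.Series(rng.normal(m, sd, len(annotation)), index=annotation.index)


def _dropout_probability(mean_log: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    # logistic in the per-gene mean, decreasing; slope=inf -> step function
    if np.isinf(cfg.dropout_slope):
        return (mean_log < cfg.dropout_midpoint).astype(float)
    return expit(cfg.dropout_slope * (cfg.dropout_midpoint - mean_log))


def simulate_cells(
    annotation: pd.DataFrame,
    clones: list,
    marker_sets: dict,
    cfg: SimulationConfig,
    baseline: pd.Series | None = None,
    rng=None,
):
    """Simulate the tumour single-cell matrix and its ground truth.

    Carcinoma cells are split evenly across ``clones`` and inherit the clone's
    copy-number track as an expression shift of
    ``cnv_attenuation * log2(CN/2)``; each population's marker genes are
    shifted up by ``marker_effect``. Observed values are exponentiated, hit by
    mean-dependent dropout, spike-ins are appended, and columns are
    renormalised to TPM (sum 1e6).

    Returns
    -------
    (ExpressionMatrix, SyntheticTruth)
    """
    for pop, genes in marker_sets.items():
        missing = set(genes) - set(annotation.index)
        if missing:
            raise ConfigurationError(f"marker genes for {pop!r} not in annotation: {sorted(missing)[:5]}")
    if cfg.cells_per_population.get("carcinoma", 0) > 0 and not clones:
        raise ConfigurationError("carcinoma cells requested but no clones supplied")

    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if baseline is None:
        baseline = draw_baseline(annotation, cfg, rng)
    baseline = baseline.reindex(annotation.index)
    G = len(annotation)
    gene_pos = {g: i for i, g in enumerate(annotation.index)}

    n_groups = max(1, len(clones))
    group_names = [f"BC{i + 1:02d}" for i in range(n_groups)]
    clone_group = {clone.clone_id: group_names[i] for i, clone in enumerate(clones)}
    clone_cn = pd.DataFrame(
        {clone.clone_id: clone.cn_track(annotation) for clone in clones},
        index=annotation.index, dtype=int,
    )

    blocks, cell_rows = [], []
    cell_counter = 0
    for pop, n_cells in cfg.cells_per_population.items():
        marker_idx = np.array([gene_pos[g] for g in marker_sets.get(pop, [])], dtype=int)
        if pop == "carcinoma":
            per_clone = np.full(len(clones), n_cells // len(clones))
            per_clone[: n_cells % len(clones)] += 1
            sub = [(clone, int(k)) for clone, k in zip(clones, per_clone) if k > 0]
        else:
            sub = [(None, n_cells)]
        for clone, k in sub:
            mean = np.repeat(baseline.values[:, None], k, axis=1)
            if clone is not None:
                cn = clone_cn[clone.clone_id].to_numpy(dtype=float)
                shift = cfg.cnv_attenuation * np.log2(np.maximum(cn, ZERO_CN_COPIES) / 2.0)
                mean += shift[:, None]
            if marker_idx.size:
                mean[marker_idx, :] += cfg.marker_effect
            value = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
            linear = np.exp2(value)
            p_drop = _dropout_probability(mean, cfg)
            linear[rng.random(mean.shape) < p_drop] = 0.0
            blocks.append(linear)
            for j in range(k):
                cid = f"C{cell_counter:04d}"
                cell_counter += 1
                if clone is not None:
                    cell_rows.append((cid, pop, clone.clone_id, clone_group[clone.clone_id]))
                else:
                    # non-carcinoma cells are spread across tumour groups
                    cell_rows.append((cid, pop, None, group_names[cell_counter % n_groups]))

    linear_all = np.concatenate(blocks, axis=1)
    n_total = linear_all.shape[1]

    spikes = np.array(cfg.spikein_copies, dtype=float)
    spike_ids = [f"{SPIKE_PREFIX}{i + 1}" for i in range(len(spikes))]
    spike_vals = spikes[:, None] * np.exp2(rng.normal(0.0, 0.1, size=(len(spikes), n_total)))
    full = np.concatenate([linear_all, spike_vals], axis=0)
    full *= 1e6 / full.sum(axis=0, keepdims=True)

    cells = pd.DataFrame(cell_rows, columns=["cell_id", "population", "clone_id", "group"]).set_index("cell_id")
    tpm = pd.DataFrame(full, index=list(annotation.index) + spike_ids, columns=cells.index)
    matrix = ExpressionMatrix(tpm=tpm, groups=cells["group"], spike_ids=tuple(spike_ids))
    return matrix, SyntheticTruth(cells=cells, clone_cn=clone_cn)


def simulate_normal_reference(
    annotation: pd.DataFrame,
    cfg: SimulationConfig,
    n_samples: int = 20,
    baseline: pd.Series | None = None,
    noise_sd: float = 0.3,
    rng=None,
) -> ExpressionMatrix:
    """Bulk normal-tissue reference samples: diploid, markerless, no dropout.

    Bulk averaging over many cells motivates the smaller noise and absent
    dropout relative to single cells.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if baseline is None:
        baseline = draw_baseline(annotation, cfg, rng)
    baseline = baseline.reindex(annotation.index)
    value = baseline.values[:, None] + rng.normal(0.0, noise_sd, size=(len(annotation), n_samples))
    linear = np.exp2(value)
    linear *= 1e6 / linear.sum(axis=0, keepdims=True)
    ids = [f"N{i:03d}" for i in range(n_samples)]
    tpm = pd.DataFrame(linear, index=annotation.index, columns=ids)
    return ExpressionMatrix(tpm=tpm, groups=pd.Series("normal", index=ids))


def simulate_experiment(
    cfg: SimulationConfig | None = None,
    n_clones: int = 3,
    segments_per_clone: int = 3,
    n_normals: int = 20,
) -> Experiment:
    """One full synthetic study: annotation, clones, markers, tumour matrix
    with truth, and a matched normal reference sharing the same baseline."""
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_clone, s_base, s_cells, s_norm = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(4)]

    annotation = make_annotation(cfg)
    n_carc = cfg.cells_per_population.get("carcinoma", 0)
    clones = []
    if n_carc > 0:
        clones = [
            simulate_clone_cnv(annotation, segments_per_clone, seed=int(s_clone) + i,
                               clone_id=f"clone{i + 1}")
            for i in range(n_clones)
        ]
    marker_sets = default_marker_sets(annotation)
    baseline = draw_baseline(annotation, cfg, np.random.default_rng(s_base))
    matrix, truth = simulate_cells(
        annotation, clones, marker_sets, cfg, baseline=baseline,
        rng=np.random.default_rng(s_cells),
    )
    normal = simulate_normal_reference(
        annotation, cfg, n_samples=n_normals, baseline=baseline,
        rng=np.random.default_rng(s_norm),
    )
    return Experiment(cfg, annotation, clones, marker_sets, matrix, truth, normal, baseline)
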