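"""Synthetic cohorts with planted ground truth.

Every pipeline input can be generated here with known truth so each
downstream stage is testable without any external download:

* a small genome with tRNA gene models and small-RNA reads containing
  planted 5'-tRFs plus non-tRNA background;
* tumor/normal tRF and mRNA expression matrices with planted differential
  expression, co-expression, and optional subtype block structure;
* clinical tables with exponential survival endpoints whose log-hazard is
  linear in planted tRF expression, uniform independent censoring,
  Gleason score correlated with the linear predictor, and log-normal PSA;
* allele-specific copy-number segment profiles with exactly planted
  large-LOH / LST / NtAI / arm-level events, and mutation tables with
  planted non-synonymous counts.

A single integer seed drives a named substream per generator, so adding a
generator never perturbs the others.  Identical seeds and configs yield
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .instability import ArmModel
from .matrix import ExpressionMatrix
from .reference import TRNAGene, TRFReference

ANTICODONS = [
    "AGC", "GGC", "TGC", "ACG", "GTT", "GTC", "CTG", "TTG", "GCC", "GTG",
    "GAT", "AAG", "TAG", "CTT", "CAT", "GAA", "TGG", "AGA", "TGA", "AGT",
    "TAC", "CCA", "GTA", "GCA", "TCC",
]

NONSYN_POOL = [
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "Splice_Site", "In_Frame_Del",
]

DRIVER_GENES = ["SPOP", "TP53", "FOXA1", "KMT2D", "PTEN", "ZMYM3", "ATM", "CDK12"]


class GenerationError(ValueError):
    """Planted events cannot be placed without conflict."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, stream name)."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort."""

    seed: int = 0
    n_tumor: int = 499
    n_normal: int = 52
    n_trf: int = 300
    n_mrna: int = 2000
    de_fraction: float = 0.2
    de_log2fc: float = 2.0
    de_up_fraction: float = 0.9
    noise_sd: float = 0.5
    n_coexpressed: int = 50
    coexpression_r: float = 0.6
    prognostic_betas: dict[str, float] = field(default_factory=dict)
    gleason_beta: float = 0.0
    censor_rate: float = 0.5
    n_subtypes: int = 1
    subtype_sizes: list[int] = field(default_factory=list)
    subtype_log2fc: float = 2.0
    n_subtype_markers: int = 15

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_trf", "n_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("de_fraction", "censor_rate", "de_up_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.n_subtypes > 1:
            if not self.subtype_sizes:
                base = self.n_tumor // self.n_subtypes
                sizes = [base] * self.n_subtypes
                sizes[-1] += self.n_tumor - base * self.n_subtypes
                self.subtype_sizes = sizes
            if sum(self.subtype_sizes) != self.n_tumor:
                raise ValueError("subtype_sizes must sum to n_tumor")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators (the oracle for every test)."""

    de_trf_ids: list[str] = field(default_factory=list)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_betas: dict[str, float] = field(default_factory=dict)
    subtype_labels: dict[str, str] = field(default_factory=dict)
    coexpressed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    hrd_components: dict[str, dict[str, int]] = field(default_factory=dict)
    arm_events: dict[str, dict[str, int]] = field(default_factory=dict)
    n_nonsynonymous: dict[str, int] = field(default_factory=dict)
    trf_abundance: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["coexpressed_pairs"] = [tuple(p) for p in raw.get("coexpressed_pairs", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome + reads
# ---------------------------------------------------------------------------

def generate_trna_genome(
    seed: int,
    n_genes: int,
    length_range: tuple[int, int] = (70, 90),
    intron_fraction: float = 0.3,
    flank: int = 50,
    n_chroms: int = 4,
) -> tuple[dict[str, str], list[TRNAGene]]:
    """Random genome with embedded tRNA gene models.

    Gene body (mature, intron excluded) lengths are drawn from
    ``length_range``, which must lie within [60, 100].  Around 30% of
    genes carry a 10-20 nt intron.  Every gene is separated from its
    neighbors and chromosome ends by at least ``flank`` nt.
    """
    lo, hi = length_range
    if not (60 <= lo <= hi <= 100):
        raise ValueError("length_range must lie within [60, 100]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "trna-genome")
    bases = np.array(list("ACGT"))
    genes: list[TRNAGene] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    genome: dict[str, str] = {}
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pieces: list[str] = []
        pos = 0
        for _ in range(per_chrom[ci]):
            gi += 1
            gap = int(rng.integers(flank, flank + 120))
            pieces.append("".join(rng.choice(bases, size=gap)))
            pos += gap
            body_len = int(rng.integers(lo, hi + 1))
            body = "".join(rng.choice(bases, size=body_len))
            introns: list[tuple[int, int]] = []
            if rng.random() < intron_fraction:
                ilen = int(rng.integers(10, 21))
                # insert after the anticodon-loop region, in the 3' half
                cut = int(rng.integers(int(body_len * 0.55), int(body_len * 0.8)))
                iseq = "".join(rng.choice(bases, size=ilen))
                body = body[:cut] + iseq + body[cut:]
                introns = [(cut + 1, cut + ilen)]
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = body
            gene_introns = introns
            if strand == "-":
                from .reference import reverse_complement

                genomic = reverse_complement(body)
                gene_introns = [
                    (len(body) - b + 1, len(body) - a + 1) for a, b in introns
                ]
            start = pos + 1
            pieces.append(genomic)
            pos += len(genomic)
            anticodon = ANTICODONS[int(rng.integers(len(ANTICODONS)))]
            genes.append(
                TRNAGene(
                    gene_id=f"tRNA-{gi:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=pos,
                    anticodon=anticodon,
                    amino_acid="",
                    intron_intervals=gene_introns,
                    source="mitochondrial" if rng.random() < 0.05 else "nuclear",
                )
            )
        tail = int(rng.integers(flank, flank + 120))
        pieces.append("".join(rng.choice(bases, size=tail)))
        genome[chrom] = "".join(pieces)
    return genome, genes


def simulate_small_rna_reads(
    reference: TRFReference,
    abundance: dict[str, float],
    background_reads: int = 0,
    seed: int = 0,
    genome: dict[str, str] | None = None,
    genes: list[TRNAGene] | None = None,
    read_length_range: tuple[int, int] = (14, 32),
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Simulate an adapter-trimmed small-RNA library.

    Planted reads are exact copies of candidate sequences with Poisson
    counts around the expected abundance.  Background reads are substrings
    of non-tRNA genome regions, rejection-sampled to never equal any
    candidate sequence.  Returns ``(reads, planted_counts)`` where reads
    are (read_id, sequence) pairs and planted_counts is the realized
    per-candidate read count (the oracle for assignment tests).
    """
    rng = _rng(seed, "small-rna-reads")
    by_id = {c.trf_id: c for c in reference.candidates}
    unknown = set(abundance) - set(by_id)
    if unknown:
        raise KeyError(f"unknown candidate ids: {sorted(unknown)}")
    candidate_seqs = reference.candidate_sequences
    reads: list[tuple[str, str]] = []
    planted: dict[str, int] = {}
    for trf_id in sorted(abundance):
        n = int(rng.poisson(abundance[trf_id]))
        planted[trf_id] = n
        seq = by_id[trf_id].sequence
        for j in range(n):
            reads.append((f"{trf_id}:{j}", seq))
    if background_reads > 0:
        if genome is None or genes is None:
            raise ValueError("background reads require the genome and gene models")
        intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        for g in genes:
            intervals[g.chrom].append((g.start, g.end))
        chroms = sorted(genome)
        emitted = 0
        attempts = 0
        while emitted < background_reads:
            attempts += 1
            if attempts > 200 * background_reads:
                raise GenerationError("cannot place background reads outside tRNA space")
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = int(rng.integers(read_length_range[0], read_length_range[1] + 1))
            start = int(rng.integers(1, len(genome[chrom]) - L + 1))
            end = start + L - 1
            if any(start <= ge and end >= gs for gs, ge in intervals[chrom]):
                continue
            seq = genome[chrom][start - 1 : end]
            if seq in candidate_seqs:
                continue
            reads.append((f"bg:{emitted}", seq))
            emitted += 1
    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm], planted


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def generate_expression_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.Series, PlantedTruth]:
    """Tumor/normal tRF (RPM) and mRNA (RPKM) matrices with planted truth.

    tRF values are log-normal: log2 RPM is Gaussian around a per-feature
    baseline, with the planted tumor-vs-normal shift of ``de_log2fc`` log2
    units on the differential features (``de_up_fraction`` of them up).
    A subset of mRNAs shares a latent factor with chosen up-regulated tRFs
    so their true Pearson correlation is ``coexpression_r``.  When
    ``n_subtypes > 1``, tumor samples get block-elevated marker features
    (``subtype_log2fc`` log2 units) on non-differential tRFs.
    """
    cfg = config
    rng = _rng(cfg.seed, "expression-cohort")
    trf_ids = [f"tRF-{i:04d}" for i in range(1, cfg.n_trf + 1)]
    gene_ids = [f"gene-{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    tumor_ids = [f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    normal_ids = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([1] * cfg.n_tumor + [0] * cfg.n_normal)

    n_de = int(round(cfg.de_fraction * cfg.n_trf))
    de_idx = rng.choice(cfg.n_trf, size=n_de, replace=False)
    n_up = int(round(cfg.de_up_fraction * n_de))
    shifts = np.zeros(cfg.n_trf)
    shifts[de_idx[:n_up]] = cfg.de_log2fc
    shifts[de_idx[n_up:]] = -cfg.de_log2fc

    base = rng.uniform(3.0, 8.0, size=cfg.n_trf)
    log2_trf = (
        base[:, None]
        + shifts[:, None] * is_tumor[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_trf, len(samples)))
    )

    truth = PlantedTruth(
        de_trf_ids=[trf_ids[i] for i in sorted(de_idx)],
        true_log2fc={trf_ids[i]: float(shifts[i]) for i in range(cfg.n_trf)},
    )

    # subtype block structure on tumor samples, planted on non-DE features
    if cfg.n_subtypes > 1:
        labels = np.repeat(
            [f"tF-{k + 1}" for k in range(cfg.n_subtypes)], cfg.subtype_sizes
        )
        non_de = np.setdiff1d(np.arange(cfg.n_trf), de_idx)
        need = cfg.n_subtype_markers * cfg.n_subtypes
        if len(non_de) < need:
            raise GenerationError("not enough non-differential features for subtype markers")
        marker_idx = rng.choice(non_de, size=need, replace=False)
        for k in range(cfg.n_subtypes):
            rows = marker_idx[k * cfg.n_subtype_markers : (k + 1) * cfg.n_subtype_markers]
            cols = np.where(labels == f"tF-{k + 1}")[0]
            log2_trf[np.ix_(rows, cols)] += cfg.subtype_log2fc
        truth.subtype_labels = dict(zip(tumor_ids, labels))

    trf_matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_trf), index=trf_ids, columns=samples), scale="RPM"
    )

    # mRNA: baseline log-normal with a latent-factor co-expressed subset
    gene_base = rng.uniform(2.0, 8.0, size=cfg.n_mrna)
    log2_mrna = gene_base[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_mrna, len(samples)))
    up_de = [i for i in de_idx[:n_up]]
    n_co = min(cfg.n_coexpressed, cfg.n_mrna)
    r = cfg.coexpression_r
    if up_de and n_co > 0:
        co_genes = rng.choice(cfg.n_mrna, size=n_co, replace=False)
        for j, gidx in enumerate(co_genes):
            tidx = up_de[j % len(up_de)]
            z = log2_trf[tidx]
            z = (z - z.mean()) / z.std()
            eps = rng.normal(0.0, 1.0, size=len(samples))
            log2_mrna[gidx] = gene_base[gidx] + (r * z + np.sqrt(1 - r**2) * eps)
            truth.coexpressed_pairs.append((trf_ids[tidx], gene_ids[gidx], float(r)))
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_mrna), index=gene_ids, columns=samples), scale="RPKM"
    )

    labels_series = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, index=samples, name="group"
    )
    return trf_matrix, mrna_matrix, labels_series, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _calibrate_censor_tau(times: np.ndarray, censor_rate: float) -> float:
    """Find tau so that C ~ U(0, tau) censors the target fraction.

    With C ~ U(0, tau), P(C < T_i) = min(T_i / tau, 1); tau solves
    mean_i min(T_i/tau, 1) = censor_rate by bisection.
    """
    lo, hi = 1e-6, float(times.max()) * 1e3

    def frac(tau: float) -> float:
        return float(np.minimum(times / tau, 1.0).mean())

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


GLEASON_LEVELS = np.array([6, 7, 8, 9, 10])
GLEASON_BASE_PROBS = np.array([0.10, 0.48, 0.13, 0.21, 0.08])


def generate_survival(
    config: CohortConfig,
    trf_matrix: ExpressionMatrix,
    baseline_median_pfs: float = 60.0,
    baseline_median_dfs: float = 72.0,
) -> pd.DataFrame:
    """Clinical table (tumor samples) with PFS and DFS endpoints.

    Event times are exponential with log-hazard = sum_i beta_i x_i over
    the planted prognostic tRFs (x = centered log2 expression), plus
    ``gleason_beta * (gleason - 7)`` when configured.  Censoring is by an
    independent uniform time calibrated to the target censor rate.
    Gleason scores are sampled from {6..10} with probabilities shifted
    along the linear predictor; PSA is log-normal; times are in months.
    """
    cfg = config
    rng = _rng(cfg.seed, "survival")
    data = trf_matrix.data
    tumor_ids = [s for s in data.columns if s.startswith("T")] or list(data.columns)
    missing = set(cfg.prognostic_betas) - set(data.index)
    if missing:
        raise KeyError(f"prognostic_betas reference unknown tRFs: {sorted(missing)}")
    n = len(tumor_ids)
    lp = np.zeros(n)
    for trf_id, beta in cfg.prognostic_betas.items():
        x = np.log2(data.loc[trf_id, tumor_ids].to_numpy(dtype=float) + 1.0)
        lp += beta * (x - x.mean())

    # Gleason correlated with the tRF linear predictor via a shifted latent
    lp_z = (lp - lp.mean()) / lp.std() if lp.std() > 0 else np.zeros(n)
    cum = np.cumsum(GLEASON_BASE_PROBS)
    from scipy.stats import norm

    thresholds = norm.ppf(np.clip(cum[:-1], 1e-9, 1 - 1e-9))
    latent = 0.8 * lp_z + rng.normal(0.0, 1.0, size=n)
    latent = (latent - latent.mean()) / latent.std() if latent.std() > 0 else latent
    gleason = GLEASON_LEVELS[np.searchsorted(thresholds, latent)]
    seven_split = rng.random(n) < 0.6  # 3+4 vs 4+3
    grade_group = np.select(
        [gleason == 6, (gleason == 7) & seven_split, (gleason == 7) & ~seven_split,
         gleason == 8, gleason >= 9],
        [1, 2, 3, 4, 5],
    )

    lp_total = lp + cfg.gleason_beta * (gleason - 7)
    psa = np.exp(2.2 + 0.25 * lp_z + rng.normal(0.0, 0.5, size=n))
    age = np.clip(rng.normal(61.0, 7.0, size=n), 40, 90).round(1)

    out = {"gleason": gleason, "grade_group": grade_group, "psa": psa.round(2), "age": age}
    for endpoint, median in (("pfs", baseline_median_pfs), ("dfs", baseline_median_dfs)):
        lam0 = np.log(2.0) / median
        t_event = rng.exponential(1.0 / (lam0 * np.exp(lp_total)))
        if cfg.censor_rate <= 0:
            time, event = t_event, np.ones(n, dtype=int)
        else:
            tau = _calibrate_censor_tau(t_event, cfg.censor_rate)
            c = rng.uniform(0.0, tau, size=n)
            event = (t_event <= c).astype(int)
            time = np.minimum(t_event, c)
        out[f"{endpoint}_time"] = np.round(time, 3)
        out[f"{endpoint}_event"] = event
    clinical = pd.DataFrame(out, index=pd.Index(tumor_ids, name="sample_id"))
    return clinical[
        ["pfs_time", "pfs_event", "dfs_time", "dfs_event", "gleason", "grade_group", "psa", "age"]
    ]


# ---------------------------------------------------------------------------
# segments + mutations
# ---------------------------------------------------------------------------

_DIPLOID = (2, 1)


def plant_segment_profile(
    planted: dict[str, int], arm_model: ArmModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Build one sample's segment profile embedding exactly the planted
    numbers of large-LOH regions, LST breakpoints, NtAI regions and
    arm-level gains/losses; the remaining genome is diploid balanced.

    Placement uses at most one event per chromosome arm; geometries are
    chosen so events never interact (an NtAI region is too short to make
    an LST, large-LOH runs are guarded by 3-10 Mb buffer segments so their
    breakpoints never qualify as LSTs, and arm-level events cover 92% of
    the arm from the centromere side so they are arm-level for LOH
    purposes and never touch a telomere).
    """
    loh = int(planted.get("loh", 0))
    n_lst = int(planted.get("lst", 0))
    n_ntai = int(planted.get("ntai", 0))
    gains = int(planted.get("gains", 0))
    losses = int(planted.get("losses", 0))
    if min(loh, n_lst, n_ntai, gains, losses) < 0:
        raise GenerationError("planted counts must be non-negative")
    events = (
        ["loh"] * loh
        + ["lst2"] * (n_lst // 2)
        + ["lst1"] * (n_lst % 2)
        + ["ntai"] * n_ntai
        + ["gain"] * gains
        + ["loss"] * losses
    )
    arms = arm_model.arms()
    if len(events) > len(arms):
        raise GenerationError(
            f"{len(events)} events do not fit on {len(arms)} arms (one event per arm)"
        )
    order = rng.permutation(len(arms))
    segments: list[tuple[str, int, int, int, int]] = []
    for event, ai in zip(events, order):
        arm = arms[ai]
        L = arm.length
        is_p = arm.name.endswith("p")  # telomere at arm.start for p arms
        tel, cen = (arm.start, arm.end) if is_p else (arm.end, arm.start)

        def span_from_tel(length: int) -> tuple[int, int]:
            return (arm.start, arm.start + length - 1) if is_p else (arm.end - length + 1, arm.end)

        def span_from_cen(length: int) -> tuple[int, int]:
            return (arm.end - length + 1, arm.end) if is_p else (arm.start, arm.start + length - 1)

        if event == "ntai":
            length = int(rng.integers(6_000_000, 9_000_001))
            s, e = span_from_tel(length)
            segments.append((arm.chrom, s, e, 3, 1))
        elif event == "lst2":
            length = 12_000_000
            off = int(L * 0.35)
            s = arm.start + off
            segments.append((arm.chrom, s, s + length - 1, 3, 1))
        elif event == "lst1":
            s, e = span_from_cen(12_000_000)
            segments.append((arm.chrom, s, e, 3, 1))
        elif event == "loh":
            run = int(rng.integers(16_000_000, 20_000_001))
            buf = 4_000_000
            off = 12_000_000  # keep clear of the telomere
            start = arm.start + off if is_p else arm.end - off - (run + 2 * buf) + 1
            b1 = (arm.chrom, start, start + buf - 1, 3, 1)
            lo = (arm.chrom, start + buf, start + buf + run - 1, 2, 0)
            b2 = (arm.chrom, start + buf + run, start + 2 * buf + run - 1, 3, 1)
            segments.extend([b1, lo, b2])
        elif event in ("gain", "loss"):
            length = int(round(0.92 * L))
            s, e = span_from_cen(length)
            state = (3, 1) if event == "gain" else (1, 0)
            segments.append((arm.chrom, s, e, *state))
    # fill the remaining genome with diploid balanced segments
    rows = []
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, s, e, t, m in segments:
        by_chrom.setdefault(chrom, []).append((s, e, t, m))
    for chrom in sorted(arm_model.chrom_length):
        L = arm_model.chrom_length[chrom]
        placed = sorted(by_chrom.get(chrom, []))
        for (s1, e1, _, _), (s2, _, _, _) in zip(placed, placed[1:]):
            if s2 <= e1:
                raise GenerationError(f"overlapping planted events on {chrom}")
        pos = 1
        for s, e, t, m in placed:
            if s > pos:
                rows.append((chrom, pos, s - 1, *_DIPLOID))
            rows.append((chrom, s, e, t, m))
            pos = e + 1
        if pos <= L:
            rows.append((chrom, pos, L, *_DIPLOID))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"])


def generate_segments_and_mutations(
    config: CohortConfig,
    arm_model: ArmModel | None = None,
    planted: dict[str, dict[str, int]] | None = None,
    mean_nonsyn: float = 40.0,
    coding_mb: float = 38.0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Segment profiles and a MAF-minimal mutation table for the tumors.

    Per-sample event counts are drawn uniformly from desk-scale ranges
    (large-LOH 0-2, LST 0-3, NtAI 0-2, arm gains/losses 0-1) unless given
    explicitly via ``planted``; non-synonymous mutation counts are Poisson
    around ``mean_nonsyn``.
    """
    arm_model = arm_model or ArmModel.synthetic()
    rng = _rng(config.seed, "segments-mutations")
    tumor_ids = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    truth = PlantedTruth()
    seg_frames = []
    maf_rows = []
    for sample in tumor_ids:
        if planted is not None and sample in planted:
            counts = dict(planted[sample])
        else:
            counts = {
                "loh": int(rng.integers(0, 3)),
                "lst": int(rng.integers(0, 4)),
                "ntai": int(rng.integers(0, 3)),
                "gains": int(rng.integers(0, 2)),
                "losses": int(rng.integers(0, 2)),
            }
        profile = plant_segment_profile(counts, arm_model, rng)
        profile.insert(0, "sample", sample)
        seg_frames.append(profile)
        truth.hrd_components[sample] = {
            "loh": counts["loh"], "lst": counts["lst"], "ntai": counts["ntai"],
        }
        truth.arm_events[sample] = {"gains": counts["gains"], "losses": counts["losses"]}
        if planted is not None and sample in planted and "n_nonsyn" in planted[sample]:
            n_nonsyn = int(planted[sample]["n_nonsyn"])
        else:
            n_nonsyn = int(rng.poisson(mean_nonsyn))
        truth.n_nonsynonymous[sample] = n_nonsyn
        n_silent = int(rng.poisson(0.25 * max(n_nonsyn, 1)))
        for k in range(n_nonsyn + n_silent):
            chrom = f"chr{int(rng.integers(1, len(arm_model.chrom_length) + 1))}"
            pos = int(rng.integers(1, arm_model.chrom_length[chrom]))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            cls = (
                NONSYN_POOL[int(rng.integers(len(NONSYN_POOL)))]
                if k < n_nonsyn
                else "Silent"
            )
            gene = DRIVER_GENES[int(rng.integers(len(DRIVER_GENES)))]
            maf_rows.append((sample, chrom, pos, ref, alt, cls, gene))
    segments = pd.concat(seg_frames, ignore_index=True)
    maf = pd.DataFrame(
        maf_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "variant_classification", "gene"],
    )
    return segments, maf, truth
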