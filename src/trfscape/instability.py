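"""Genomic-instability scoring from allele-specific copy-number segments.

Per-sample scores:

* TMB — non-synonymous somatic mutations per megabase of coding sequence.
* HRD — sum of three DNA-based instability counts: large (>15 Mb)
  non-arm-level LOH regions, large-scale state transitions (LST:
  breakpoints flanked on both sides by >10 Mb segments after 3 Mb
  smoothing), and subtelomeric allelic-imbalance regions (NtAI).
* Aneuploidy score (AS) — arm-level gains plus losses relative to the
  sample ploidy (length-weighted modal total copy number).
* Segment count — raw number of segment records.

Segments are (chrom, start, end, total_cn, minor_cn), 1-based inclusive,
non-overlapping and sorted within a chromosome.  LOH/LST/NtAI are counted
per chromosome arm (segments clipped to arms), so runs crossing the
centromere never merge across it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats

logger = logging.getLogger(__name__)

NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)

KNOWN_CLASSES = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "3'UTR",
    "5'UTR",
    "Intron",
    "IGR",
    "RNA",
    "3'Flank",
    "5'Flank",
}


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str  # e.g. "chr1p"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ArmModel:
    """Chromosome-arm geometry: lengths, centromeres, excluded arms."""

    def __init__(self, table: pd.DataFrame, excluded_arms: set[str] | None = None):
        required = {"chrom", "length", "cen_start", "cen_end"}
        if not required <= set(table.columns):
            raise ValueError(f"arm model table needs columns {sorted(required)}")
        self.table = table.reset_index(drop=True)
        self.excluded_arms = set(excluded_arms or set())
        if "excluded_arms" in table.columns:
            for _, row in table.iterrows():
                val = row["excluded_arms"]
                if isinstance(val, str) and val.strip():
                    for a in val.split(","):
                        self.excluded_arms.add(f"{row['chrom']}{a.strip()}")
        self.chrom_length = dict(zip(table["chrom"], table["length"].astype(int)))
        self.centromere = {
            row["chrom"]: (int(row["cen_start"]), int(row["cen_end"]))
            for _, row in table.iterrows()
        }
        for chrom, (cs, ce) in self.centromere.items():
            if not (1 <= cs <= ce <= self.chrom_length[chrom]):
                raise ValueError(f"{chrom}: centromere outside chromosome")

    def arms(self, include_excluded: bool = False) -> list[Arm]:
        out = []
        for chrom, L in self.chrom_length.items():
            cs, ce = self.centromere[chrom]
            for name, start, end in ((f"{chrom}p", 1, cs - 1), (f"{chrom}q", ce + 1, L)):
                if end < start:
                    continue
                if not include_excluded and name in self.excluded_arms:
                    continue
                out.append(Arm(chrom=chrom, name=name, start=start, end=end))
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArmModel":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def synthetic(cls) -> "ArmModel":
        """The shipped 4-chromosome desk-scale model (no excluded arms)."""
        with resources.files("trfscape.data").joinpath("arm_model.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segment helpers
# ---------------------------------------------------------------------------

def _clip_to_arm(segments: pd.DataFrame, arm: Arm) -> pd.DataFrame:
    seg = segments[segments["chrom"] == arm.chrom]
    seg = seg[(seg["end"] >= arm.start) & (seg["start"] <= arm.end)].copy()
    seg["start"] = seg["start"].clip(lower=arm.start)
    seg["end"] = seg["end"].clip(upper=arm.end)
    return seg.sort_values("start").reset_index(drop=True)


def _merge_equal_state(rows: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Merge consecutive (start, end, total, minor) rows with equal state."""
    merged: list[list[int]] = []
    for s, e, t, m in rows:
        if merged and merged[-1][2] == t and merged[-1][3] == m:
            merged[-1][1] = e
        else:
            merged.append([s, e, t, m])
    return [tuple(r) for r in merged]


# ---------------------------------------------------------------------------
# HRD components
# ---------------------------------------------------------------------------

def loh_large(
    segments: pd.DataFrame,
    arm_model: ArmModel,
    min_len: float = 15e6,
    arm_level_fraction: float = 0.9,
) -> int:
    """Large non-arm-level LOH: per arm, maximal runs of contiguous LOH
    segments (minor_cn = 0, total_cn >= 1) longer than ``min_len`` that
    cover less than ``arm_level_fraction`` of the arm."""
    count = 0
    for arm in arm_model.arms():
        seg = _clip_to_arm(segments, arm)
        runs: list[tuple[int, int]] = []
        cur: tuple[int, int] | None = None
        for _, row in seg.iterrows():
            is_loh = row["minor_cn"] == 0 and row["total_cn"] >= 1
            if is_loh:
                if cur is not None and row["start"] == cur[1] + 1:
                    cur = (cur[0], int(row["end"]))
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = (int(row["start"]), int(row["end"]))
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        for s, e in runs:
            length = e - s + 1
            if length > min_len and length < arm_level_fraction * arm.length:
                count += 1
    return count


def lst(
    segments: pd.DataFrame,
    arm_model: ArmModel,
    min_seg: float = 10e6,
    smooth_below: float = 3e6,
) -> int:
    """Large-scale state transitions: per arm, after removing segments
    shorter than ``smooth_below`` and merging equal-state neighbors, count
    breakpoints whose two flanking segments are each longer than
    ``min_seg`` and differ in copy state."""
    count = 0
    for arm in arm_model.arms():
        seg = _clip_to_arm(segments, arm)
        rows = [
            (int(r["start"]), int(r["end"]), int(r["total_cn"]), int(r["minor_cn"]))
            for _, r in seg.iterrows()
            if (r["end"] - r["start"] + 1) >= smooth_below
        ]
        rows = _merge_equal_state(rows)
        for left, right in zip(rows, rows[1:]):
            len_l = left[1] - left[0] + 1
            len_r = right[1] - right[0] + 1
            if len_l > min_seg and len_r > min_seg and (left[2], left[3]) != (right[2], right[3]):
                count += 1
    return count


def ntai(
    segments: pd.DataFrame, arm_model: ArmModel, telomere_tol: int = 0
) -> int:
    """Subtelomeric allelic imbalance: segments with total_cn != 2*minor_cn
    that reach a chromosome terminus (within ``telomere_tol`` bp) and do
    not cross the centromere."""
    count = 0
    for _, row in segments.iterrows():
        chrom = row["chrom"]
        if chrom not in arm_model.chrom_length:
            continue
        if row["total_cn"] == 2 * row["minor_cn"]:
            continue
        L = arm_model.chrom_length[chrom]
        cs, ce = arm_model.centromere[chrom]
        touches = row["start"] <= 1 + telomere_tol or row["end"] >= L - telomere_tol
        crosses_cen = row["start"] <= ce and row["end"] >= cs
        if touches and not crosses_cen:
            count += 1
    return count


def hrd_score(segments: pd.DataFrame, arm_model: ArmModel, **kwargs) -> dict:
    """HRD = large LOH + LST + NtAI for one sample's profile."""
    loh = loh_large(segments, arm_model, **{k: v for k, v in kwargs.items() if k in ("min_len", "arm_level_fraction")})
    l = lst(segments, arm_model, **{k: v for k, v in kwargs.items() if k in ("min_seg", "smooth_below")})
    n = ntai(segments, arm_model, **{k: v for k, v in kwargs.items() if k in ("telomere_tol",)})
    return {"loh_count": loh, "lst_count": l, "ntai_count": n, "hrd": loh + l + n}


# ---------------------------------------------------------------------------
# aneuploidy / segments / TMB
# ---------------------------------------------------------------------------

def aneuploidy_score(
    segments: pd.DataFrame, arm_model: ArmModel, arm_fraction: float = 0.8
) -> dict:
    """Ploidy-adjusted arm-level gains and losses.

    Ploidy is the length-weighted modal total_cn rounded to the nearest
    integer (robust to focal amplification); an arm is gained (lost) when
    at least ``arm_fraction`` of its assayed length lies above (below)
    ploidy.  AS = gains + losses over non-excluded arms.
    """
    lengths = (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)
    if lengths.size == 0:
        return {"ploidy": 2, "gains": 0, "losses": 0, "aneuploidy_score": 0}
    weights: dict[int, float] = {}
    for cn, w in zip(segments["total_cn"].astype(int), lengths):
        weights[cn] = weights.get(cn, 0.0) + w
    ploidy = int(round(max(weights, key=lambda cn: weights[cn])))
    gains = losses = 0
    for arm in arm_model.arms():
        seg = _clip_to_arm(segments, arm)
        if seg.empty:
            continue
        seg_len = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
        assayed = seg_len.sum()
        above = seg_len[(seg["total_cn"] > ploidy).to_numpy()].sum()
        below = seg_len[(seg["total_cn"] < ploidy).to_numpy()].sum()
        if above >= arm_fraction * assayed:
            gains += 1
        elif below >= arm_fraction * assayed:
            losses += 1
    return {"ploidy": ploidy, "gains": gains, "losses": losses, "aneuploidy_score": gains + losses}


def segment_count(segments: pd.DataFrame) -> int:
    """Raw number of segment records (no equal-state merging applied)."""
    return int(len(segments))


def tmb(mutations: pd.DataFrame, sample: str | None = None, coding_mb: float = 38.0) -> float:
    """Non-synonymous somatic mutations per megabase of coding sequence."""
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    muts = mutations if sample is None else mutations[mutations["sample"] == sample]
    classes = muts["variant_classification"]
    unknown = set(classes) - KNOWN_CLASSES
    if unknown:
        logger.warning("unknown variant classifications counted as synonymous: %s", sorted(unknown))
    n_nonsyn = classes.isin(NONSYNONYMOUS_CLASSES).sum()
    return float(n_nonsyn) / coding_mb


def score_profiles(
    segments: pd.DataFrame,
    arm_model: ArmModel,
    mutations: pd.DataFrame | None = None,
    coding_mb: float = 38.0,
    **kwargs,
) -> pd.DataFrame:
    """Per-sample InstabilityScores table from a multi-sample segment file."""
    rows = []
    for sample, seg in segments.groupby("sample", sort=True):
        seg = seg.sort_values(["chrom", "start"]).reset_index(drop=True)
        scores = hrd_score(seg, arm_model, **kwargs)
        scores.update(aneuploidy_score(seg, arm_model))
        scores["n_segments"] = segment_count(seg)
        scores["sample_id"] = sample
        if mutations is not None:
            scores["tmb"] = tmb(mutations, sample=sample, coding_mb=coding_mb)
        rows.append(scores)
    df = pd.DataFrame(rows).set_index("sample_id")
    cols = ["loh_count", "lst_count", "ntai_count", "hrd", "ploidy", "gains", "losses", "aneuploidy_score", "n_segments"]
    if mutations is not None:
        cols.append("tmb")
    return df[cols]


# ---------------------------------------------------------------------------
# log-ratio SEG support (no allele-specific information)
# ---------------------------------------------------------------------------

SEG_LOGRATIO_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]


def read_seg_logratio(path) -> pd.DataFrame:
    """Read a standard log2-ratio SEG file (sample, chrom, start, end,
    seg_mean).  This dialect carries no allele-specific state, so it
    supports only segment counting and total-copy gain/loss calls."""
    df = pd.read_csv(path, sep="\t")
    rename = {
        "ID": "sample", "Sample": "sample", "Chromosome": "chrom",
        "Start": "start", "End": "end", "Segment_Mean": "seg_mean",
    }
    df = df.rename(columns=rename)
    missing = set(SEG_LOGRATIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    return df[SEG_LOGRATIO_COLUMNS].astype({"start": int, "end": int, "seg_mean": float})


def call_gains_losses(
    seg: pd.DataFrame, threshold: float = 0.3
) -> pd.DataFrame:
    """Per-sample counts of gained / lost segments from log2 ratios
    (|seg_mean| above the threshold) plus the raw segment count."""
    rows = []
    for sample, s in seg.groupby("sample", sort=True):
        rows.append(
            {
                "sample_id": sample,
                "gained_segments": int((s["seg_mean"] >= threshold).sum()),
                "lost_segments": int((s["seg_mean"] <= -threshold).sum()),
                "n_segments": int(len(s)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# subtype summaries
# ---------------------------------------------------------------------------

def driver_frequency_tables(
    labels: pd.Series, status: pd.DataFrame, exact: bool = False
) -> dict[str, dict]:
    """Per-gene 2 x k (yes/no by subtype) contingency tables with Pearson
    chi-squared p (df = k-1) and per-subtype prevalence percentages.

    ``labels`` maps sample -> subtype; ``status`` is samples x genes
    boolean (fusion/mutation present).
    """
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two subtypes")
    shared = labels.index.intersection(status.index)
    out: dict[str, dict] = {}
    for gene in status.columns:
        yes = [int(status.loc[shared, gene][labels.loc[shared] == g].sum()) for g in groups]
        tot = [int((labels.loc[shared] == g).sum()) for g in groups]
        no = [t - y for t, y in zip(tot, yes)]
        table = pd.DataFrame([yes, no], index=["yes", "no"], columns=groups)
        out[gene] = stats.contingency_summary(table, exact=exact)
    return out


def group_score_comparison(scores: pd.Series, labels: pd.Series) -> dict:
    """Omnibus Kruskal-Wallis plus BH-adjusted pairwise rank-sum tests
    (with figure-style significance stars) of a score across subtypes."""
    groups = sorted(labels.unique())
    shared = scores.index.intersection(labels.index)
    values = {g: scores.loc[shared][labels.loc[shared] == g].to_numpy() for g in groups}
    kw_stat, kw_p = stats.kruskal_test([values[g] for g in groups])
    pairs = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            _, p = stats.rank_sum_test(values[a], values[b])
            pairs.append({"group_a": a, "group_b": b, "p_value": p})
    pair_df = pd.DataFrame(pairs)
    if not pair_df.empty:
        pair_df["fdr"] = stats.bh_adjust(pair_df["p_value"])
        pair_df["stars"] = pair_df["fdr"].map(stats.significance_stars)
    return {"kruskal_statistic": kw_stat, "kruskal_p": kw_p, "pairwise": pair_df}
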