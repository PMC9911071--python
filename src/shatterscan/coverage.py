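"""Binned read-dosage analysis on the relative-coverage (diploid = 2) scale.

Reads are counted in consecutive non-overlapping bins; sample bins are
normalized to pooled diploid controls so a diploid region sits near 2,
a heterozygous deletion near 1 and a single-copy gain near 3. A dense
cluster of copy-number-variant bins marks a shattered region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

DEFAULT_CONTROL_FLOOR = 10


@dataclass
class BinGrid:
    """Per-chromosome raw read counts on a fixed bin grid."""

    bin_size: int
    lengths: dict[str, int]
    counts: dict[str, np.ndarray]

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def congruent(self, other: "BinGrid") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.lengths == other.lengths
        )


def bin_counts(sam_path: str, bin_size: int = 5000, lengths: dict[str, int] | None = None) -> BinGrid:
    """Count primary mapped reads per bin by leftmost mapped coordinate."""
    if bin_size < 1000:
        raise ValueError("bin_size must be >= 1 kb")
    with pysam.AlignmentFile(sam_path, "r") as sam:
        ref_lengths = {n: ln for n, ln in zip(sam.references, sam.lengths)}
        if lengths is None:
            lengths = ref_lengths
        counts = {
            n: np.zeros(-(-ln // bin_size), dtype=np.int64) for n, ln in lengths.items()
        }
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if chrom not in counts:
                raise ValueError(f"chromosome {chrom!r} absent from genome table")
            counts[chrom][rec.reference_start // bin_size] += 1
    return BinGrid(bin_size, dict(lengths), counts)


def pool(grids: list[BinGrid]) -> BinGrid:
    """Sum congruent control grids (pooled-control normalization)."""
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise ValueError("control grids are not congruent")
    counts = {
        n: sum(g.counts[n] for g in grids) for n in first.counts
    }
    return BinGrid(first.bin_size, first.lengths, counts)


def normalize(
    sample: BinGrid, control: BinGrid, control_floor: int = DEFAULT_CONTROL_FLOOR
) -> pd.DataFrame:
    """Relative coverage per bin on the diploid = 2 scale.

    Each bin's sample/control count ratio is calibrated so that the
    genome-wide *median* ratio maps to 2: as long as most of the genome is
    diploid, diploid bins sit at 2 and single-copy gains/losses at 3/1
    regardless of how much extra material the sample carries (a
    total-count calibration would deflate the diploid baseline when a
    large trisomic segment inflates the sample total). Bins with control
    count below control_floor are masked (NaN relative).
    """
    if not sample.congruent(control):
        raise ValueError("sample and control bin grids are not congruent")
    if sample.total() == 0 or control.total() == 0:
        raise ValueError("empty alignment input")
    ratios = []
    per_chrom = {}
    for chrom in sample.counts:
        sc = sample.counts[chrom].astype(float)
        cc = control.counts[chrom].astype(float)
        masked = cc < control_floor
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = sc / cc
        ratio[masked] = np.nan
        per_chrom[chrom] = (ratio, masked)
        ratios.append(ratio[~masked])
    all_ratios = np.concatenate(ratios)
    scale = float(np.median(all_ratios))
    if scale == 0:
        raise ValueError("median sample/control ratio is zero")
    # one refinement pass: CNV bins shift the raw median slightly, so
    # re-estimate the scale from the bins that classify as diploid
    cn = np.rint(2 * all_ratios / scale)
    diploid = all_ratios[cn == 2]
    if len(diploid) >= 10:
        scale = float(np.median(diploid))
    rows = []
    for chrom, ln in sample.lengths.items():
        ratio, masked = per_chrom[chrom]
        rel = 2.0 * ratio / scale
        n = len(ratio)
        starts = np.arange(n) * sample.bin_size
        ends = np.minimum(starts + sample.bin_size, ln)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "raw_count": sample.counts[chrom],
                    "relative_coverage": rel,
                    "masked": masked,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def call_cnv_bins(
    rel_bins: pd.DataFrame, low: float = 1.5, high: float = 2.5
) -> pd.DataFrame:
    """Per-bin state: loss (< low), gain (> high), else neutral; masked bins NA."""
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    out = rel_bins.copy()
    rel = out["relative_coverage"]
    state = np.where(rel < low, "loss", np.where(rel > high, "gain", "neutral"))
    state = np.where(out["masked"], "masked", state)
    out["state"] = state
    return out


def find_cnv_cluster(
    cnv_bins: pd.DataFrame, min_span: int = 500_000, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Dense-CNV regions: maximal runs where a sliding window of min_span
    bins has at least min_fraction CNV (loss/gain) bins. Sorted by span,
    longest first."""
    clusters = []
    for chrom, sub in cnv_bins.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        bin_size = int((sub["end"] - sub["start"]).iloc[0])
        w = max(1, min_span // bin_size)
        is_cnv = sub["state"].isin(["loss", "gain"]).to_numpy().astype(float)
        if len(is_cnv) < 1:
            continue
        if len(is_cnv) <= w:
            frac = np.array([is_cnv.mean()])
            hot_windows = frac >= min_fraction
            starts_idx = [0] if hot_windows[0] else []
            window_len = len(is_cnv)
        else:
            kernel = np.ones(w) / w
            frac = np.convolve(is_cnv, kernel, mode="valid")
            hot_windows = frac >= min_fraction
            starts_idx = np.flatnonzero(hot_windows)
            window_len = w
        if len(starts_idx) == 0:
            continue
        # merge overlapping hot windows into maximal runs of bins
        hot_bins = np.zeros(len(is_cnv), dtype=bool)
        for i in starts_idx:
            hot_bins[i : i + window_len] = True
        idx = np.flatnonzero(hot_bins)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.r_[idx[0], idx[breaks + 1]]
        run_ends = np.r_[idx[breaks], idx[-1]]
        for rs, re_ in zip(run_starts, run_ends):
            # trim padding: clip the run to its first/last CNV bin
            run_cnv = np.flatnonzero(is_cnv[rs : re_ + 1])
            if len(run_cnv) == 0:
                continue
            rs, re_ = rs + run_cnv[0], rs + run_cnv[-1]
            n_cnv = int(is_cnv[rs : re_ + 1].sum())
            clusters.append(
                {
                    "chrom": chrom,
                    "start": int(sub["start"].iloc[rs]),
                    "end": int(sub["end"].iloc[re_]),
                    "n_cnv_bins": n_cnv,
                    "fraction_cnv_bins": n_cnv / (re_ - rs + 1),
                }
            )
    df = pd.DataFrame(
        clusters, columns=["chrom", "start", "end", "n_cnv_bins", "fraction_cnv_bins"]
    )
    if len(df):
        df = df.assign(span=df["end"] - df["start"]).sort_values(
            "span", ascending=False
        ).drop(columns="span").reset_index(drop=True)
    return df


def write_tsv(cnv_bins: pd.DataFrame, path: str) -> None:
    out = cnv_bins.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive in reports
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def plot_dosage(rel_bins: pd.DataFrame, path: str) -> None:
    """Per-chromosome dot plot of relative coverage (dosage plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = rel_bins["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = rel_bins[rel_bins["chrom"] == chrom]
        ax.plot(sub["start"] / 1e6, sub["relative_coverage"], ".", ms=2)
        for y in (1, 2, 3):
            ax.axhline(y, color="grey", lw=0.5, ls=":")
        ax.set_ylim(0, 4.5)
        ax.set_ylabel("relative coverage")
        ax.set_title(chrom, fontsize=9)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
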