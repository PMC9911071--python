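"""Parental allele-frequency analysis and meiotic-origin inference.

In a cross of an A/B hybrid female (e.g. Col-0/Ler-1) to a homozygous A
male, the parent-B allele fraction in the offspring reads out chromosome
copy composition: 1/2 for a balanced {A,B} region, 1/3 for a trisomic
{A,A,B} region, 2/3 for {A,B,B} and 0 for {A,A}. A trisomic region that
mixes 1/2 and 1/3 states carries two *different* maternal haplotypes —
the signature of meiosis-I nondisjunction — whereas meiosis-II
nondisjunction co-transmits sister chromatids of the same haplotype,
giving 2/3 or 0. The pericentromeric subregion, where crossovers are
rare, is weighted decisively.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import pysam

DEFAULT_BIN_SIZE = 10_000
DEFAULT_READ_FLOOR = 20
DEFAULT_TOL = 0.06
STATES = (0.0, 1 / 3, 1 / 2, 2 / 3)


@dataclass
class MeiosisCall:
    region: tuple[str, int, int]
    states_observed: dict[str, float]  # state label -> fraction of bins
    verdict: str  # meiosis_I | meiosis_II | balanced | inconclusive
    evidence: str


# ---------------------------------------------------------------------------
# pileup-level operations


def allele_counts_from_sam(
    sam_path: str, snps: list[tuple[str, int, str, str]]
) -> pd.DataFrame:
    """Counts of parent-A and parent-B alleles at diagnostic SNPs.

    Equivalent to a parsed-mpileup restricted to the SNP sites: walks
    primary alignments and tallies, at each covered diagnostic site, reads
    carrying the A allele and reads carrying the B allele. snps rows are
    (chrom, pos 0-based, alleleA, alleleB).
    """
    by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
    for chrom, pos, a, b in snps:
        by_chrom.setdefault(chrom, {})[pos] = (a, b)
    pos_sorted = {c: np.array(sorted(d)) for c, d in by_chrom.items()}
    counts: dict[tuple[str, int], list[int]] = {}
    with pysam.AlignmentFile(sam_path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if chrom not in pos_sorted:
                continue
            start = rec.reference_start
            seq = rec.query_sequence
            end = start + len(seq)
            arr = pos_sorted[chrom]
            lo = np.searchsorted(arr, start)
            hi = np.searchsorted(arr, end)
            for pos in arr[lo:hi]:
                a, b = by_chrom[chrom][int(pos)]
                base = seq[pos - start]
                key = (chrom, int(pos))
                if key not in counts:
                    counts[key] = [0, 0]
                if base == a:
                    counts[key][0] += 1
                elif base == b:
                    counts[key][1] += 1
    rows = [
        {"chrom": c, "pos": p, "reads_A": v[0], "reads_B": v[1]}
        for (c, p), v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "reads_A", "reads_B"])


def allele_counts_from_records(
    records: list[dict], snps: list[tuple[str, int, str, str]]
) -> pd.DataFrame:
    """Same tally as allele_counts_from_sam, from in-memory alignment
    records (as produced by the read simulator) without a SAM round-trip."""
    by_chrom: dict[str, dict[int, tuple[str, str]]] = {}
    for chrom, pos, a, b in snps:
        by_chrom.setdefault(chrom, {})[pos] = (a, b)
    pos_sorted = {c: np.array(sorted(d)) for c, d in by_chrom.items()}
    counts: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        chrom = rec["chrom"]
        if chrom not in pos_sorted:
            continue
        arr = pos_sorted[chrom]
        for key in ("mate1", "mate2"):
            start, _strand, seq = rec[key]
            lo = np.searchsorted(arr, start)
            hi = np.searchsorted(arr, start + len(seq))
            for pos in arr[lo:hi]:
                a, b = by_chrom[chrom][int(pos)]
                base = seq[pos - start]
                k = (chrom, int(pos))
                if k not in counts:
                    counts[k] = [0, 0]
                if base == a:
                    counts[k][0] += 1
                elif base == b:
                    counts[k][1] += 1
    rows = [
        {"chrom": c, "pos": p, "reads_A": v[0], "reads_B": v[1]}
        for (c, p), v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "reads_A", "reads_B"])


def select_diagnostic_snps(
    parentA_counts: pd.DataFrame,
    parentB_counts: pd.DataFrame,
    min_depth: int = 10,
    max_minor: float = 0.1,
) -> pd.DataFrame:
    """Sites where each homozygous parent is near-fixed for a different allele.

    Input frames carry chrom, pos, and per-base counts (columns A, C, G, T).
    Keeps sites with depth >= min_depth in both parents, minor-allele
    fraction <= max_minor in each, and different major alleles.
    """
    bases = ["A", "C", "G", "T"]

    def major(df: pd.DataFrame) -> pd.DataFrame:
        m = df[bases].to_numpy(dtype=float)
        depth = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = m / depth[:, None]
        top = np.argmax(m, axis=1)
        top_frac = frac[np.arange(len(df)), top]
        out = df[["chrom", "pos"]].copy()
        out["allele"] = [bases[i] for i in top]
        out["depth"] = depth
        out["minor"] = 1 - top_frac
        return out

    a = major(parentA_counts)
    b = major(parentB_counts)
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_A", "_B"))
    keep = (
        (merged["depth_A"] >= min_depth)
        & (merged["depth_B"] >= min_depth)
        & (merged["minor_A"] <= max_minor)
        & (merged["minor_B"] <= max_minor)
        & (merged["allele_A"] != merged["allele_B"])
    )
    out = merged.loc[keep, ["chrom", "pos", "allele_A", "allele_B"]]
    return out.rename(columns={"allele_A": "alleleA", "allele_B": "alleleB"})


# ---------------------------------------------------------------------------
# binning and expectation


def binned_allele_freq(
    allele_counts: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_SIZE,
    floor: int = DEFAULT_READ_FLOOR,
) -> pd.DataFrame:
    """Per-bin parent-B allele fraction, pooling read counts across SNPs.

    Pooling is read-weighted (total B reads / total informative reads per
    bin), not a per-SNP average, so deep and shallow sites contribute in
    proportion to their evidence. Bins with fewer than `floor` informative
    reads are masked.
    """
    df = allele_counts.copy()
    df["bin"] = df["pos"] // bin_size
    g = df.groupby(["chrom", "bin"], sort=True).agg(
        n_snps=("pos", "size"), reads_A=("reads_A", "sum"), reads_B=("reads_B", "sum")
    ).reset_index()
    g["start"] = g["bin"] * bin_size
    g["end"] = g["start"] + bin_size
    g["reads_total"] = g["reads_A"] + g["reads_B"]
    with np.errstate(invalid="ignore", divide="ignore"):
        g["freq_B"] = g["reads_B"] / g["reads_total"]
    g.loc[g["reads_total"] < floor, "freq_B"] = np.nan
    g["masked"] = g["reads_total"] < floor
    return g[["chrom", "start", "end", "n_snps", "reads_B", "reads_total",
              "freq_B", "masked"]]


def expected_allele_frequency(copies: list[str] | tuple[str, ...]) -> Fraction:
    """Exact parent-B allele fraction for a multiset of haplotype labels.

    {A,B} -> 1/2; {A,A,B} -> 1/3; {A,B,B} -> 2/3; {A,A} -> 0.
    """
    if len(copies) == 0:
        raise ValueError("need at least one copy")
    if any(c not in ("A", "B") for c in copies):
        raise ValueError("haplotype labels must be 'A' or 'B'")
    return Fraction(sum(c == "B" for c in copies), len(copies))


def classify_bins(
    freq_bins: pd.DataFrame,
    states: tuple[float, ...] = STATES,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Nearest-state assignment of each unmasked bin, 'other' beyond tol."""
    gaps = np.diff(sorted(states))
    if tol >= gaps.min() / 2:
        raise ValueError("tol must be below half the minimal state gap")
    out = freq_bins.copy()
    labels = []
    for f in out["freq_B"]:
        if np.isnan(f):
            labels.append("masked")
            continue
        dists = [abs(f - s) for s in states]
        i = int(np.argmin(dists))
        labels.append(f"{states[i]:.3f}" if dists[i] <= tol else "other")
    out["state"] = labels
    return out


def infer_stage(
    classified: pd.DataFrame,
    trisomic_region: tuple[str, int, int],
    pericentromere: tuple[str, int, int] | None = None,
    min_state_fraction: float = 0.1,
    relative_coverage: float | None = None,
) -> MeiosisCall:
    """Meiotic origin of the extra chromosome from per-bin frequency states.

    meiosis_I: both the 1/2 and 1/3 states occur across the trisomic
    region (two different maternal haplotypes co-inherited). meiosis_II:
    the 2/3 or 0 states dominate (identical sister chromatids). balanced:
    uniformly 1/2, or uniformly 0 (maternal parent-A transmission) when
    the region's relative coverage says it is disomic — allele frequency
    alone cannot distinguish a disomic A,A region from an A,A,A trisomy,
    so pass the dosage estimate from the coverage stage when available.
    The pericentromeric subregion, if given, is decisive: its states alone
    determine the verdict when they are conclusive, because crossovers
    rarely alter pericentromeric haplotype.
    """
    chrom, start, end = trisomic_region
    disomic = relative_coverage is not None and relative_coverage < 2.5

    def region_states(reg):
        c, s, e = reg
        sub = classified[
            (classified["chrom"] == c)
            & (classified["start"] >= s)
            & (classified["end"] <= e)
            & (~classified["masked"])
        ]
        n = len(sub)
        if n == 0:
            return {}
        return {
            k: v / n for k, v in sub["state"].value_counts().items()
        }

    s_half = f"{1 / 2:.3f}"
    s_third = f"{1 / 3:.3f}"
    s_two_thirds = f"{2 / 3:.3f}"
    s_zero = f"{0.0:.3f}"

    def verdict_from(raw_fracs: dict[str, float]) -> str:
        if not raw_fracs:
            return "inconclusive"
        # renormalize over the recognized dosage states: a few bins pushed
        # past tol by sampling noise ("other") should not veto a verdict,
        # but a mostly-unrecognizable region is inconclusive
        known = {k: v for k, v in raw_fracs.items() if k != "other"}
        total = sum(known.values())
        if total < 0.5:
            return "inconclusive"
        fracs = {k: v / total for k, v in known.items()}
        has = lambda k: fracs.get(k, 0.0) >= min_state_fraction
        if has(s_half) and has(s_third):
            return "meiosis_I"
        if fracs.get(s_half, 0.0) > 0.9:
            return "balanced"
        if fracs.get(s_zero, 0.0) > 0.9 and disomic:
            return "balanced"  # maternal parent-A transmission, two copies
        if has(s_two_thirds) or (has(s_zero) and (has(s_half) or not disomic)):
            return "meiosis_II"
        if has(s_third):
            # trisomy with only the 1/3 state visible: extra copy present
            # everywhere and haplotype-distinct -> still meiosis I pattern
            return "meiosis_I"
        return "inconclusive"

    region_fracs = region_states(trisomic_region)
    verdict = verdict_from(region_fracs)
    evidence = f"trisomic region states: {region_fracs}"
    if pericentromere is not None:
        peri_fracs = region_states(pericentromere)
        peri_verdict = verdict_from(peri_fracs)
        if peri_verdict != "inconclusive":
            verdict = peri_verdict
            evidence += f"; pericentromeric states (decisive): {peri_fracs}"
    return MeiosisCall(trisomic_region, region_fracs, verdict, evidence)


def plot_allele_freq(freq_bins: pd.DataFrame, path: str) -> None:
    """Dot plot of parent-B allele fraction per bin along each chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = freq_bins["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = freq_bins[freq_bins["chrom"] == chrom]
        ax.plot(sub["start"] / 1e6, sub["freq_B"] * 100, ".", ms=3)
        for y in (0, 100 / 3, 50, 200 / 3):
            ax.axhline(y, color="grey", lw=0.5, ls=":")
        ax.set_ylim(-5, 105)
        ax.set_ylabel("% parent-B alleles")
        ax.set_title(chrom, fontsize=9)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
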