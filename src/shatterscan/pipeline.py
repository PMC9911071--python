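"""End-to-end orchestration: simulate -> coverage -> junctions ->
reconstruct -> haplotypes -> enrichment, from a single config, with a
summary report of the headline descriptors (junction census, breakpoint
spacing, repair-class and orientation percentages, meiosis verdict,
per-track enrichment)."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import coverage as cov
from . import enrichment as enr
from . import haplotypes as hap
from . import junctions as jn
from . import reconstruct as rec
from . import simulate as sim

logger = logging.getLogger(__name__)


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"n_chroms": 1, "lengths": [2_000_000], "gc": 0.36},
    "snp_rate": 0.001,
    "shatter": {
        "region": [300_000, 1_000_000],
        "n_fragments": 12,
        "loss_fraction": 0.1,
        "repair_mix": {"microhomology": 0.638, "perfect": 0.112, "insertion": 0.25},
    },
    "stage": "meiosis_I",
    "reads": {"depth": 30.0, "read_len": 100, "insert_mean": 300.0, "insert_sd": 50.0},
    "coverage": {"bin_size": 5000, "low": 1.5, "high": 2.5,
                 "min_span": 100_000, "min_fraction": 0.2},
    "junctions": {"min_distance": 2000, "radius": 500},
    "haplotypes": {"bin_size": 10_000, "floor": 20, "tol": 0.06},
    "enrichment": {"windows": [1000, 10_000], "n_perm": 1000,
                   "gene_fraction": 0.45, "gene_mean_len": 2500},
}


@dataclass
class SummaryReport:
    n_junctions: int = 0
    fraction_both_breakpoints_in_cluster: float | None = None
    breakpoint_spacing_kb: float | None = None
    n_chains: int = 0
    longest_chain_junctions: int = 0
    repair_class_percent: dict = field(default_factory=dict)
    orientation_percent: dict = field(default_factory=dict)
    inverted_percent: float | None = None
    meiosis_verdict: str = "inconclusive"
    enrichment: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def report_fractions(
    calls_table: pd.DataFrame,
    cluster_region: tuple[str, int, int] | None,
    gene_track: enr.AnnotationTrack | None = None,
    window: int = 0,
) -> dict:
    """Census ratios: junctions with both breakpoints inside the cluster,
    and breakpoints inside gene sequence (counted 2 per junction)."""
    out: dict = {"n_junctions": int(len(calls_table))}
    if len(calls_table) == 0:
        out["fraction_both_in_cluster"] = None
        out["fraction_breakpoints_in_genes"] = None
        return out
    if cluster_region is not None:
        chrom, start, end = cluster_region
        both = (
            (calls_table["chrom1"] == chrom)
            & (calls_table["chrom2"] == chrom)
            & calls_table["pos1"].between(start + 1, end)
            & calls_table["pos2"].between(start + 1, end)
        )
        out["fraction_both_in_cluster"] = float(both.mean())
    if gene_track is not None:
        bps = [
            (r["chrom1"], int(r["pos1"])) for _, r in calls_table.iterrows()
        ] + [(r["chrom2"], int(r["pos2"])) for _, r in calls_table.iterrows()]
        inside = [
            _point_in_track(gene_track, c, p - 1) for c, p in bps
        ]
        out["fraction_breakpoints_in_genes"] = float(np.mean(inside))
    return out


def _point_in_track(track: enr.AnnotationTrack, chrom: str, pos0: int) -> bool:
    if chrom not in track.starts:
        return False
    e = track.ends[chrom]
    s = track.starts[chrom]
    i = np.searchsorted(e, pos0, side="right")
    return bool(i < len(s) and s[i] <= pos0)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run(config: dict | None = None, outdir: str | None = None) -> SummaryReport:
    """Run the full simulated analysis described by config.

    Every stochastic step derives its seed from config['seed']; rerunning
    with the same config reproduces the same report.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=2)

    # --- simulate
    g = cfg["genome"]
    genome0 = sim.make_genome(g["n_chroms"], g["lengths"], g["gc"], seeds[0])
    shat = cfg["shatter"]
    chrom = genome0.names[0]
    region = (chrom, shat["region"][0], shat["region"][1])
    genome, event, _ = sim.shatter(
        genome0, region, shat["n_fragments"], shat["loss_fraction"],
        shat["repair_mix"], seed=seeds[1],
    )
    haps = sim.derive_haplotypes(genome, cfg["snp_rate"], seeds[2])
    kary = sim.make_offspring(genome, haps, event, cfg["stage"], seeds[3])
    rd = cfg["reads"]
    paths = {}
    _, srecords = sim.simulate_reads(genome, haps, kary, rd["depth"], rd["read_len"],
                                     rd["insert_mean"], rd["insert_sd"], seeds[4])
    balanced = sim.Karyotype(
        [sim.ChromosomeCopy(n, "A", None, "maternal") for n in genome.names]
        + [sim.ChromosomeCopy(n, "B", None, "paternal") for n in genome.names],
        "balanced",
    )
    if outdir:
        tmpdir = outdir
    else:
        import tempfile

        tmpdir = tempfile.mkdtemp(prefix="shatterscan_")
    sample_sam = os.path.join(tmpdir, "sample.sam")
    sim.write_sam(srecords, genome, sample_sam)
    control_sams = []
    for i in range(2):
        _, crec = sim.simulate_reads(genome, haps, balanced, rd["depth"], rd["read_len"],
                                     rd["insert_mean"], rd["insert_sd"], seeds[5] + i)
        p = os.path.join(tmpdir, f"control{i + 1}.sam")
        sim.write_sam(crec, genome, p)
        control_sams.append(p)

    # --- coverage
    cc = cfg["coverage"]
    sample_bins = cov.bin_counts(sample_sam, cc["bin_size"])
    control_bins = cov.pool([cov.bin_counts(p, cc["bin_size"]) for p in control_sams])
    rel = cov.normalize(sample_bins, control_bins)
    states = cov.call_cnv_bins(rel, cc["low"], cc["high"])
    clusters = cov.find_cnv_cluster(states, cc["min_span"], cc["min_fraction"])
    if outdir:
        cov.write_tsv(states, os.path.join(outdir, "coverage_bins.tsv"))
        cov.plot_dosage(rel, os.path.join(outdir, "dosage.png"))
    if len(clusters):
        top = clusters.iloc[0]
        cluster_region = (top["chrom"], int(top["start"]), int(top["end"]))
    else:
        cluster_region = region

    # --- junctions
    jc = cfg["junctions"]
    calls, jlog = jn.call_junctions(
        sample_sam, control_sams, genome, jc["min_distance"], jc["radius"]
    )
    logger.info("junction calling: %s", jlog)
    table = jn.calls_to_table(calls)
    if outdir:
        table.to_csv(os.path.join(outdir, "junctions.tsv"), sep="\t", index=False)
        jn.write_bedpe(calls, os.path.join(outdir, "junctions.bedpe"))

    # --- reconstruct
    graph = rec.build_segment_graph(calls, cluster_region)
    chains = rec.chain(graph)
    if outdir:
        rec.chains_to_table(chains).to_csv(
            os.path.join(outdir, "chains.tsv"), sep="\t", index=False
        )
        if chains:
            rec.chain_diagram_svg(chains[0], os.path.join(outdir, "longest_chain.svg"))

    # --- haplotypes
    hc = cfg["haplotypes"]
    counts = hap.allele_counts_from_sam(
        sample_sam, [(c, p, a, b) for c, p, a, b in haps.snps]
    )
    freq = hap.binned_allele_freq(counts, hc["bin_size"], hc["floor"])
    classified = hap.classify_bins(freq, tol=hc["tol"])
    peri_lo = (region[1] + 2 * region[2]) // 3
    in_cluster = rel[
        (rel["chrom"] == cluster_region[0])
        & (rel["start"] >= cluster_region[1])
        & (rel["end"] <= cluster_region[2])
        & (~rel["masked"])
    ]
    mean_rel = float(in_cluster["relative_coverage"].mean()) if len(in_cluster) else None
    meiosis = hap.infer_stage(
        classified, region, (chrom, peri_lo, region[2]),
        relative_coverage=mean_rel,
    )
    if outdir:
        freq.to_csv(os.path.join(outdir, "allele_freq_bins.tsv"), sep="\t", index=False)
        hap.plot_allele_freq(freq, os.path.join(outdir, "allele_freq.png"))

    # --- enrichment
    ec = cfg["enrichment"]
    tracks = sim.make_tracks(
        genome, {"gene": (ec["gene_fraction"], ec["gene_mean_len"])}, seeds[6]
    )
    gene_track = enr.AnnotationTrack.from_intervals("gene", tracks["gene"])
    bps = [bp for c in calls for bp in c.breakpoints]
    etable = pd.DataFrame()
    if bps:
        etable = enr.enrichment_table(
            bps, [gene_track], genome.lengths, tuple(ec["windows"]),
            ec["n_perm"], constraint=(chrom, cluster_region[1] + 1, cluster_region[2]),
            seed=seeds[7],
        )
        if outdir:
            etable.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)

    # --- report
    report = SummaryReport()
    report.n_junctions = len(calls)
    fr = report_fractions(table, cluster_region, gene_track)
    report.fraction_both_breakpoints_in_cluster = fr.get("fraction_both_in_cluster")
    if bps:
        try:
            report.breakpoint_spacing_kb = jn.breakpoint_density(
                bps, (chrom, cluster_region[1] + 1, cluster_region[2])
            )
        except ValueError:
            report.breakpoint_spacing_kb = None
    report.n_chains = len(chains)
    report.longest_chain_junctions = max((c.n_junctions for c in chains), default=0)
    if len(table):
        report.repair_class_percent = {
            k: round(100 * v, 1)
            for k, v in table["repair_class"].value_counts(normalize=True).items()
        }
        report.orientation_percent = {
            k: round(100 * v, 1)
            for k, v in table["orientation_class"].value_counts(normalize=True).items()
        }
        report.inverted_percent = round(
            100 * table["orientation_class"].isin(["head_head", "tail_tail"]).mean(), 1
        )
    report.meiosis_verdict = meiosis.verdict
    report.enrichment = etable.to_dict("records") if len(etable) else []
    n_matched, n_truth, n_calls, _ = jn.match_calls_to_truth(calls, event.junctions_truth)
    report.truth = {
        "stage": cfg["stage"],
        "n_truth_junctions": n_truth,
        "junction_recall": n_matched / n_truth if n_truth else None,
        "junction_precision": n_matched / n_calls if n_calls else None,
    }
    if outdir:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
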