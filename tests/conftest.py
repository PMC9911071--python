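"""Shared fixtures: one moderately sized shattered-chromosome simulation,
with idealized alignments written as SAM, reused across detection tests."""

from __future__ import annotations

import os

import pytest

from shatterscan import simulate as sim


class ShatterFixture:
    """Bundle of a simulated dataset and its ground truth."""

    def __init__(self, tmpdir: str, seed: int = 12):
        self.region = ("chr1", 200_000, 700_000)
        g0 = sim.make_genome(1, [1_000_000], gc=0.36, seed=seed)
        self.genome, self.event, self.rearranged = sim.shatter(
            g0, self.region, n_fragments=13, loss_fraction=0.1, seed=seed + 1
        )
        self.haplotypes = sim.derive_haplotypes(self.genome, 0.001, seed=seed + 2)
        self.karyotype = sim.make_offspring(
            self.genome, self.haplotypes, self.event, "meiosis_I", seed=seed + 3
        )
        self.readset, self.records = sim.simulate_reads(
            self.genome, self.haplotypes, self.karyotype, depth=30.0, seed=seed + 4
        )
        self.sample_sam = os.path.join(tmpdir, "sample.sam")
        sim.write_sam(self.records, self.genome, self.sample_sam)
        balanced = sim.make_offspring(
            self.genome, self.haplotypes, None, "balanced", seed=seed + 5
        )
        self.control_sams = []
        for i in range(2):
            _, recs = sim.simulate_reads(
                self.genome, self.haplotypes, balanced, depth=30.0, seed=seed + 6 + i
            )
            path = os.path.join(tmpdir, f"control{i + 1}.sam")
            sim.write_sam(recs, self.genome, path)
            self.control_sams.append(path)


@pytest.fixture(scope="session")
def shatter_sim(tmp_path_factory) -> ShatterFixture:
    tmpdir = tmp_path_factory.mktemp("shatter_sim")
    return ShatterFixture(str(tmpdir))


@pytest.fixture(scope="session")
def junction_calls(shatter_sim):
    from shatterscan import junctions as jn

    calls, log = jn.call_junctions(
        shatter_sim.sample_sam, shatter_sim.control_sams, shatter_sim.genome
    )
    return calls, log
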