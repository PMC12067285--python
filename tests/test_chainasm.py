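"""Junction walking, chain assembly and the exhaustive-search oracle."""

import numpy as np
import pandas as pd
import pytest

from hgtscan import chainasm
from hgtscan.chainasm import Block, Breakend, Junction, assemble_chain, summarize_element
from hgtscan.errors import ChainBranchingError, ConfigError
from tests.conftest import DATA_DIR


def segments_frame(segs):
    return pd.DataFrame(segs, columns=["chrom", "start", "end"])


def junctions_for_chain(blocks):
    """Derive the junction set joining consecutive oriented blocks."""
    out = []
    for a, b in zip(blocks[:-1], blocks[1:]):
        (ca, sa, ea, oa), (cb, sb, eb, ob) = a, b
        exit_be = Breakend(ca, ea, "right") if oa == "+" else Breakend(ca, sa + 1, "left")
        entry_be = Breakend(cb, sb + 1, "left") if ob == "+" else Breakend(cb, eb, "right")
        out.append(Junction(exit_be, entry_be, support=10))
    return out


def random_chain(rng, n_blocks):
    """Random oriented chain of disjoint segments on a few chromosomes."""
    chroms = ["chr1", "chr2", "chr3"]
    used = {c: 1_000_000 for c in chroms}
    blocks = []
    for _ in range(n_blocks):
        c = chroms[int(rng.integers(len(chroms)))]
        start = used[c]
        length = int(rng.integers(3, 40)) * 100_000
        blocks.append((c, start, start + length, "+" if rng.random() < 0.5 else "-"))
        used[c] = start + length + 2_000_000  # keep breakends well separated
    return blocks


def exhaustive_oracle(segments, junctions, seed_key):
    """Enumerate every ordering/orientation of the segments consistent with
    the junction set, starting at the seed terminus.

    Depth-first over all remaining segments with consistency pruning — an
    exhaustive search of the ordering space, independent of the walk logic.
    """
    n = len(segments)
    ends = {}
    for i, r in segments.reset_index(drop=True).iterrows():
        ends[(i, "left")] = (r["chrom"], int(r["start"]) + 1, "left")
        ends[(i, "right")] = (r["chrom"], int(r["end"]), "right")
    jset = set()
    for j in junctions:
        a = (j.a.chrom, j.a.pos, j.a.side)
        b = (j.b.chrom, j.b.pos, j.b.side)
        jset.add(frozenset([a, b]))

    def joined(key_a, key_b):
        return frozenset([ends[key_a], ends[key_b]]) in jset

    results = []

    def extend(path):
        # path: list of (segment index, orientation)
        i, orient = path[-1]
        exit_key = (i, "right" if orient == "+" else "left")
        partners = [
            (k, "+" if k[1] == "left" else "-")
            for k in ends
            if k[0] not in {p[0] for p in path} and joined(exit_key, k)
        ]
        if not partners:
            # valid terminus only if the exit end joins nothing at all
            if not any(joined(exit_key, k) for k in ends if k[0] != i):
                results.append(list(path))
            return
        for key, next_orient in partners:
            extend(path + [(key[0], next_orient)])

    seg_i, entry_side = seed_key
    extend([(seg_i, "+" if entry_side == "left" else "-")])
    return results


class TestAssembly:
    def test_two_segments_one_junction(self):
        blocks = [("chr1", 1_000_000, 2_000_000, "+"), ("chr2", 5_000_000, 5_500_000, "-")]
        segs = segments_frame([b[:3] for b in blocks])
        chain = assemble_chain(junctions_for_chain(blocks), segs,
                               seed_terminus=("chr1", 1_000_001, "left"))
        assert [(b.chrom, b.orientation) for b in chain.blocks] == [("chr1", "+"), ("chr2", "-")]
        assert chain.total_length == 1_500_000

    def test_published_topology_fixture(self):
        """Synthetic stand-in for the published junction table: 11 blocks on
        six chromosomes, 15 Mb, centromere-to-centromere."""
        from hgtscan import io

        junctions = io.read_bedpe(DATA_DIR / "nht1_junctions_synthetic.bedpe")
        segs = pd.read_csv(DATA_DIR / "nht1_segments_synthetic.bed", sep="\t",
                           names=["chrom", "start", "end"])
        chain = assemble_chain(junctions, segs, seed_terminus=("chr21", 100_001, "left"))
        summary = summarize_element(chain)
        assert summary.n_blocks == 11
        assert summary.n_chromosomes == 6
        assert summary.termini == ("centromeric", "centromeric")
        assert 14_500_000 <= summary.total_length <= 15_500_000
        assert chain.blocks[0].chrom == "chr21"
        assert chain.blocks[-1].chrom == "chr7"

    def test_matches_exhaustive_oracle(self):
        """Across 100 random chains of 2-8 blocks the walk agrees with an
        exhaustive enumeration over orderings and orientations."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            blocks = random_chain(rng, int(rng.integers(2, 9)))
            segs = segments_frame([b[:3] for b in blocks])
            junctions = junctions_for_chain(blocks)
            first = blocks[0]
            seed_be = (
                (first[0], first[1] + 1, "left") if first[3] == "+" else (first[0], first[2], "right")
            )
            chain = assemble_chain(junctions, segs, seed_terminus=seed_be)
            got = [(b.chrom, b.start, b.end, b.orientation) for b in chain.blocks]
            assert got == blocks
            # oracle agreement: the enumeration finds exactly this chain
            seg_lookup = {(c, s, e): i for i, (c, s, e) in enumerate(
                segs.itertuples(index=False, name=None))}
            seed_key = (seg_lookup[first[:3]], "left" if first[3] == "+" else "right")
            solutions = exhaustive_oracle(segs, junctions, seed_key)
            assert len(solutions) == 1
            oracle_blocks = [
                (segs["chrom"].iat[i], segs["start"].iat[i], segs["end"].iat[i], o)
                for i, o in solutions[0]
            ]
            assert oracle_blocks == blocks

    def test_palindromic_symmetry(self):
        """Walking from the opposite terminus reverses the block order and
        flips every orientation."""
        rng = np.random.default_rng(11)
        blocks = random_chain(rng, 6)
        segs = segments_frame([b[:3] for b in blocks])
        junctions = junctions_for_chain(blocks)
        first, last = blocks[0], blocks[-1]
        fwd = assemble_chain(
            junctions, segs,
            seed_terminus=(first[0], first[1] + 1, "left") if first[3] == "+" else (first[0], first[2], "right"),
        )
        rev = assemble_chain(
            junctions, segs,
            seed_terminus=(last[0], last[2], "right") if last[3] == "+" else (last[0], last[1] + 1, "left"),
        )
        flipped = [
            Block(b.chrom, b.start, b.end, "+" if b.orientation == "-" else "-", i)
            for i, b in enumerate(reversed(fwd.blocks))
        ]
        assert rev.blocks == flipped

    def test_tolerance_invariance(self):
        """Total length is stable for any matching tolerance below the
        smallest gap between distinct breakends."""
        blocks = [("chr1", 1_000_000, 2_000_000, "+"), ("chr2", 5_000_000, 5_500_000, "+")]
        segs = segments_frame([b[:3] for b in blocks])
        junctions = junctions_for_chain(blocks)
        lengths = {
            assemble_chain(junctions, segs, ("chr1", 1_000_001, "left"), tolerance=tol).total_length
            for tol in (0, 1000, 5000, 50_000)
        }
        assert lengths == {1_500_000}

    def test_branching_error_lists_breakends(self):
        blocks = [("chr1", 1_000_000, 2_000_000, "+"),
                  ("chr2", 5_000_000, 5_500_000, "+"),
                  ("chr3", 8_000_000, 8_400_000, "+")]
        segs = segments_frame([b[:3] for b in blocks])
        j1 = junctions_for_chain(blocks[:2])
        # second junction re-uses chr1's right end -> branching
        j2 = [Junction(Breakend("chr1", 2_000_000, "right"), Breakend("chr3", 8_000_001, "left"), 10)]
        with pytest.raises(ChainBranchingError, match="chr1:2000000"):
            assemble_chain(j1 + j2, segs, ("chr1", 1_000_001, "left"))

    def test_circular_element_reported(self):
        blocks = [("chr1", 1_000_000, 2_000_000, "+"), ("chr2", 5_000_000, 5_500_000, "+")]
        segs = segments_frame([b[:3] for b in blocks])
        junctions = junctions_for_chain(blocks)
        # close the loop: last exit joins first entry
        junctions.append(
            Junction(Breakend("chr2", 5_500_000, "right"), Breakend("chr1", 1_000_001, "left"), 8)
        )
        chain = assemble_chain(junctions, segs)
        assert chain.circular
        assert len(chain.blocks) == 2

    def test_min_support_filters_junctions(self):
        blocks = [("chr1", 1_000_000, 2_000_000, "+"), ("chr2", 5_000_000, 5_500_000, "-")]
        segs = segments_frame([b[:3] for b in blocks])
        weak = [Junction(j.a, j.b, support=2) for j in junctions_for_chain(blocks)]
        chain = assemble_chain(weak, segs, ("chr1", 1_000_001, "left"))
        assert len(chain.blocks) == 1  # junction discarded below min support


class TestSummary:
    def test_single_block(self):
        chain = chainasm.ChainElement(
            [Block("chr1", 0, 1_000_000, "+", 0)], termini=("centromeric", "internal")
        )
        s = summarize_element(chain)
        assert (s.n_blocks, s.n_chromosomes, s.total_length) == (1, 1, 1_000_000)

    def test_empty_chain_rejected(self):
        with pytest.raises(ConfigError):
            summarize_element(chainasm.ChainElement([]))

    def test_simulated_chain_matches_truth(self, default_cohort):
        """Chain assembled from the simulated junctions equals the planted
        block list (order, orientation, span)."""
        from hgtscan import cpgclock

        cohort = default_cohort
        carriers = cohort.truth.carrier_ids
        noncarriers = [t for t in cohort.tumor_ids if t not in carriers]
        segs = cpgclock.select_informative_segments(cohort.cn_segments, carriers, noncarriers)
        chain = assemble_chain(cohort.junctions, segs, chrom_lengths=cohort.chrom_lengths)
        truth = cohort.truth.planted_blocks
        got = chainasm.chain_to_frame(chain)
        assert summarize_element(chain).total_length == int((truth["end"] - truth["start"]).sum())
        assert len(got) == len(truth)
        # the walk may start from either terminus; normalise direction
        if got["chrom"].iat[0] != truth["chrom"].iat[0]:
            got = got.iloc[::-1].reset_index(drop=True)
            got["orientation"] = got["orientation"].map({"+": "-", "-": "+"})
        pd.testing.assert_frame_equal(
            got[["chrom", "start", "end", "orientation"]],
            truth[["chrom", "start", "end", "orientation"]].reset_index(drop=True),
        )
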