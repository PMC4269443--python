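"""Two-pass translated screen: recovery, specificity, thresholds, monotonicity."""

import numpy as np
import pytest

import bilescreen as bs
from bilescreen import _seq as sq
from bilescreen.search import EmptySearchDatabaseError, search_sample, two_pass_screen
from bilescreen.synthetic import random_genome, true_gene_hits


def _sample_from_reads(reads, sample_id="t"):
    mat = np.stack([sq.encode_nt(r) for r in reads])
    return bs.SampleReadSet(sample_id=sample_id, group="", read_matrix=mat)


@pytest.fixture(scope="module")
def error_free_sample(community_small):
    profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
    return bs.simulate_sample(
        community_small.genomes, profile, 20_000, err=0.0, seed=31, sample_id="ef"
    )


class TestBroadScreen:
    def test_in_gene_reads_recovered_with_full_identity(
        self, community_small, error_free_sample
    ):
        """Every error-free read fully inside a gene locus is recovered at
        identity 1.0 in exactly one frame."""
        s = error_free_sample
        truth = true_gene_hits(s, community_small.genomes, min_overlap=75)
        combined = bs.ProteinFamilyDB(
            [r for r in community_small.proteins if r.family in ("BSH", "HSDH")]
        )
        cand, hits = bs.broad_screen(s, combined)
        fully_inside = set(
            truth[truth["family"].isin(["BSH", "HSDH"])]["read_index"]
        )
        assert fully_inside <= set(cand)
        best = hits.set_index("read_index")
        for ri in list(fully_inside)[:200]:
            assert best.loc[ri, "identity"] == 1.0

    def test_exactly_one_perfect_frame(self, community_small, error_free_sample):
        s = error_free_sample
        truth = true_gene_hits(s, community_small.genomes, min_overlap=75)
        ri = int(truth[truth["family"] == "BSH"]["read_index"].iloc[0])
        pid = truth[truth["family"] == "BSH"]["protein_id"].iloc[0]
        prot = community_small.proteins[pid].sequence
        frames = bs.six_frame_translate(s.read_seq(ri))
        perfect = [f for f, pep in frames.items() if pep.strip("*") and pep in prot]
        assert len(perfect) == 1

    def test_background_false_positive_rate_below_one_percent(self, rng):
        """Reads from gene-free uniform-random sequence are almost never hits."""
        genome = random_genome(np.random.default_rng(77), 30_000)
        db = bs.AnnotatedGenomeDB(
            [bs.GenomeRecord("bg", genome, ("P", "F", "S"))]
        )
        s = bs.simulate_sample(
            db, bs.CommunityProfile({"bg": 1.0}), 10_000, err=0.0, seed=78
        )
        proteins = bs.build_community(genome_len=8_000).proteins
        combined = bs.ProteinFamilyDB(
            [r for r in proteins if r.family in ("BSH", "HSDH")]
        )
        cand, _ = bs.broad_screen(s, combined)
        assert len(cand) / 10_000 < 0.01

    def test_empty_database_is_configuration_error(self, error_free_sample):
        with pytest.raises(EmptySearchDatabaseError):
            bs.broad_screen(error_free_sample, bs.ProteinFamilyDB([]))

    def test_short_reads_rejected_upstream(self, community_small):
        s = _sample_from_reads(["ACGT" * 10])  # 40 nt < 75
        with pytest.raises(ValueError, match="below the minimum"):
            bs.broad_screen(s, community_small.proteins)


class TestThresholds:
    def _synthetic_pair(self, rng, n_sub):
        """A read whose +1 translation matches a DB protein except n_sub sites."""
        prot = sq.random_protein(rng, 40)
        pep = list(prot[5:30])  # 25 aa window
        for i in np.linspace(2, 22, n_sub).astype(int):
            pep[i] = "A" if pep[i] != "A" else "G"
        read_nt = bs.synthetic.reverse_translate("".join(pep), rng)
        db = bs.ProteinFamilyDB(
            [bs.ProteinRecord("target", "BSH", prot)]
        )
        return _sample_from_reads([read_nt]), db

    def test_boundary_identity_is_inclusive(self, rng):
        """A hit at exactly the threshold identity is retained (>= convention)."""
        sample, db = self._synthetic_pair(rng, 0)
        hits = search_sample(sample, db, 1.0, 24, exhaustive=True)
        assert len(hits) == 1 and hits["identity"].iloc[0] == 1.0

    def test_per_family_thresholds_differ(self, rng):
        """~70% identity fails the BSH cutoff (0.75) but passes ADH's (0.60)."""
        prot = sq.random_protein(np.random.default_rng(5), 40)
        pep = list(prot[5:30])
        for i in np.linspace(2, 22, 7).astype(int):  # 18/25 = 0.72
            pep[i] = "A" if pep[i] != "A" else "G"
        read_nt = bs.synthetic.reverse_translate("".join(pep), np.random.default_rng(6))
        sample = _sample_from_reads([read_nt])
        cfg = bs.SearchConfig()
        db_bsh = bs.ProteinFamilyDB([bs.ProteinRecord("t", "BSH", prot)])
        db_adh = bs.ProteinFamilyDB([bs.ProteinRecord("t", "ADH", prot)])
        hits_bsh = search_sample(
            sample, db_bsh, cfg.strict_min_identity("BSH"), 24, exhaustive=True
        )
        hits_adh = search_sample(
            sample, db_adh, cfg.strict_min_identity("ADH"), 24, exhaustive=True
        )
        assert len(hits_bsh) == 0
        assert len(hits_adh) == 1

    def test_monotonicity_in_identity_threshold(self, community_small, error_free_sample):
        counts = []
        for t in (0.35, 0.5, 0.75, 0.9):
            hits = search_sample(
                error_free_sample, community_small.proteins, t, 24
            )
            counts.append(len(hits))
        assert counts == sorted(counts, reverse=True)


class TestTwoPass:
    def test_stringent_subset_of_broad(self, community_small, error_free_sample):
        combined = bs.ProteinFamilyDB(
            [r for r in community_small.proteins if r.family in ("BSH", "HSDH")]
        )
        cand, _ = bs.broad_screen(error_free_sample, combined)
        strict = two_pass_screen(error_free_sample, community_small.proteins)
        strict_bh = strict[strict["family"].isin(["BSH", "HSDH"])]
        assert set(strict_bh["read_index"]) <= set(cand)

    def test_identity_degrades_with_error_rate(self, community_small):
        profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
        means = []
        for e in (0.0, 0.01, 0.05):
            s = bs.simulate_sample(
                community_small.genomes, profile, 20_000, err=e, seed=41
            )
            hits = two_pass_screen(s, community_small.proteins)
            means.append(hits["identity"].mean())
        assert means[0] > means[1] > means[2]

    def test_seeded_matches_exhaustive_on_small_sample(self, community_small):
        profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
        s = bs.simulate_sample(
            community_small.genomes, profile, 400, err=0.01, seed=51
        )
        a = two_pass_screen(s, community_small.proteins)
        b = two_pass_screen(s, community_small.proteins, exhaustive=True)
        key = ["read_index", "family", "protein_id", "score"]
        assert a[key].reset_index(drop=True).equals(b[key].reset_index(drop=True))

    def test_best_hit_tiebreak_is_deterministic(self, rng):
        prot = sq.random_protein(rng, 40)
        read_nt = bs.synthetic.reverse_translate(prot[5:30], rng)
        db = bs.ProteinFamilyDB(
            [bs.ProteinRecord("b_second", "BSH", prot),
             bs.ProteinRecord("a_first", "BSH", prot)]
        )
        hits = search_sample(_sample_from_reads([read_nt]), db, 0.75, 24,
                             exhaustive=True)
        assert list(hits["protein_id"]) == ["a_first"]
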