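"""Nucleotide taxonomy assignment: accuracy, thresholds, LCA tie handling."""

import numpy as np
import pytest

import bilescreen as bs
from bilescreen import _seq as sq
from bilescreen.refdb import GeneLocus
from bilescreen.synthetic import random_genome
from bilescreen.taxonomy import (
    EmptyGenomeDatabaseError,
    assign_reads,
    summarize_assignment_rate,
)


def _sample_from_reads(reads, sample_id="t"):
    mat = np.stack([sq.encode_nt(r) for r in reads])
    return bs.SampleReadSet(sample_id=sample_id, group="", read_matrix=mat)


@pytest.fixture(scope="module")
def tiny_db(rng):
    g1 = random_genome(np.random.default_rng(100), 4000)
    g2 = random_genome(np.random.default_rng(101), 4000)
    return bs.AnnotatedGenomeDB(
        [
            bs.GenomeRecord("gA", g1, ("Firmicutes", "Lachnospiraceae", "SpeciesA")),
            bs.GenomeRecord("gB", g2, ("Firmicutes", "Lachnospiraceae", "SpeciesB")),
        ]
    )


class TestAssignRead:
    @pytest.mark.parametrize("method", ["seeded", "exhaustive"])
    def test_exact_read_assigned_with_identity_one(self, tiny_db, method):
        read = tiny_db["gA"].sequence[1000:1075]
        s = _sample_from_reads([read])
        out = assign_reads(s, [0], tiny_db, method=method)
        row = out.iloc[0]
        assert row["genome_id"] == "gA"
        assert row["nt_identity"] == 1.0
        assert (row["phylum"], row["tax_family"], row["species"]) == (
            "Firmicutes", "Lachnospiraceae", "SpeciesA",
        )
        assert (row["genome_start"], row["genome_end"]) == (1000, 1075)

    @pytest.mark.parametrize("method", ["seeded", "exhaustive"])
    def test_reverse_strand_read_assigned(self, tiny_db, method):
        read = sq.revcomp(tiny_db["gA"].sequence[2000:2075])
        out = assign_reads(_sample_from_reads([read]), [0], tiny_db, method=method)
        assert out.iloc[0]["genome_id"] == "gA"
        assert out.iloc[0]["strand"] == "-"

    def test_heavily_mutated_read_unassigned(self, tiny_db):
        read = list(tiny_db["gA"].sequence[1000:1075])
        rng = np.random.default_rng(3)
        for i in rng.choice(75, size=38, replace=False):
            read[i] = "ACGT"[("ACGT".index(read[i]) + 1) % 4]
        out = assign_reads(
            _sample_from_reads(["".join(read)]), [0], tiny_db, method="exhaustive"
        )
        assert out.iloc[0]["genome_id"] == ""
        assert out.iloc[0]["species"] == ""

    def test_tie_between_same_family_genomes_blanks_species(self):
        """A region shared verbatim by two genomes of one family resolves at
        the family rank (LCA), never by an arbitrary species pick."""
        rng = np.random.default_rng(7)
        shared = random_genome(rng, 400)
        gA = random_genome(rng, 2000) + shared
        gB = random_genome(rng, 2000) + shared
        db = bs.AnnotatedGenomeDB(
            [
                bs.GenomeRecord("gA", gA, ("Firmicutes", "Lachnospiraceae", "SpeciesA")),
                bs.GenomeRecord("gB", gB, ("Firmicutes", "Lachnospiraceae", "SpeciesB")),
            ]
        )
        read = shared[100:175]
        for method in ("seeded", "exhaustive"):
            out = assign_reads(_sample_from_reads([read]), [0], db, method=method)
            row = out.iloc[0]
            assert row["n_tied_genomes"] == 2
            assert row["species"] == ""
            assert row["tax_family"] == "Lachnospiraceae"
            assert row["phylum"] == "Firmicutes"

    def test_tie_across_families_blanks_family_keeps_phylum(self):
        rng = np.random.default_rng(8)
        shared = random_genome(rng, 400)
        db = bs.AnnotatedGenomeDB(
            [
                bs.GenomeRecord("gA", random_genome(rng, 1000) + shared,
                                ("Firmicutes", "Lachnospiraceae", "SpeciesA")),
                bs.GenomeRecord("gB", random_genome(rng, 1000) + shared,
                                ("Firmicutes", "Clostridiaceae", "SpeciesB")),
            ]
        )
        out = assign_reads(_sample_from_reads([shared[:75]]), [0], db,
                           method="exhaustive")
        row = out.iloc[0]
        assert row["phylum"] == "Firmicutes"
        assert row["tax_family"] == "" and row["species"] == ""

    def test_empty_db_is_configuration_error(self, tiny_db):
        s = _sample_from_reads([tiny_db["gA"].sequence[:75]])
        with pytest.raises(EmptyGenomeDatabaseError):
            assign_reads(s, [0], bs.AnnotatedGenomeDB([]))


class TestAccuracy:
    def test_error_free_species_accuracy_is_total(self, community_small):
        profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
        s = bs.simulate_sample(community_small.genomes, profile, 3000,
                               err=0.0, seed=61)
        idx = np.arange(300)
        out = assign_reads(s, idx, community_small.genomes)
        assert (out["genome_id"] != "").all()
        true_species = [
            community_small.genomes.genomes[g].species
            for g in s.origin_genome[idx]
        ]
        assert (out["species"].to_numpy() == np.array(true_species)).all()

    def test_family_accuracy_bounds_species_accuracy_with_errors(self, community_small):
        profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
        s = bs.simulate_sample(community_small.genomes, profile, 3000,
                               err=0.05, seed=62)
        idx = np.arange(500)
        out = assign_reads(s, idx, community_small.genomes)
        assigned = out[out["genome_id"] != ""]
        sel = assigned["read_index"].to_numpy()
        true_g = [community_small.genomes.genomes[g] for g in s.origin_genome[sel]]
        sp_acc = np.mean([r.species == g.species for (_, r), g in zip(assigned.iterrows(), true_g)])
        fam_acc = np.mean([r.tax_family == g.tax_family for (_, r), g in zip(assigned.iterrows(), true_g)])
        assert fam_acc >= sp_acc


class TestAssignmentRate:
    def test_all_assignable_gives_equal_counts(self, community_small, analysis_small):
        sid = "control_001"
        hits = analysis_small.hit_tables[sid]
        asg = analysis_small.assignments[sid]
        rates = summarize_assignment_rate(hits, asg)
        assert (rates["assigned_hits"] <= rates["total_hits"]).all()

    def test_withheld_genomes_halve_assignment_rate(self, community_small):
        """Dropping the source genomes of ~half the BSH hits from the
        reference drops assigned/total accordingly (ground-truth oracle)."""
        profile = bs.CommunityProfile(bs.BASE_WEIGHTS)
        s = bs.simulate_sample(community_small.genomes, profile, 30_000,
                               err=0.0, seed=63)
        hits = bs.two_pass_screen(s, community_small.proteins)
        bsh_hits = hits[hits["family"] == "BSH"]
        # withhold genomes contributing roughly half the BSH hits
        origins = s.origin_genome[bsh_hits["read_index"].to_numpy()]
        counts = np.bincount(origins, minlength=len(community_small.genomes.genomes))
        order = np.argsort(counts)[::-1]
        target = counts.sum() / 2
        withheld, acc = set(), 0
        for gi in order:
            if acc >= target:
                break
            withheld.add(gi)
            acc += counts[gi]
        partial = bs.AnnotatedGenomeDB(
            [g for i, g in enumerate(community_small.genomes.genomes) if i not in withheld]
        )
        asg = bs.assign_hit_reads(s, bsh_hits, partial)
        rates = summarize_assignment_rate(bsh_hits, asg)
        expected = 1 - acc / counts.sum()
        frac = rates["assigned_hits"].iloc[0] / rates["total_hits"].iloc[0]
        n = rates["total_hits"].iloc[0]
        tol = 3 * np.sqrt(expected * (1 - expected) / n) + 0.02
        assert abs(frac - expected) <= tol

    def test_empty_hit_table(self):
        import pandas as pd

        rates = summarize_assignment_rate(
            pd.DataFrame(columns=["read_index", "family"]), pd.DataFrame()
        )
        assert len(rates) == 0
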