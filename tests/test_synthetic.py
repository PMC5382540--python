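import numpy as np
import pytest

from redoxmir.config import DEFAULT_ADAPTER
from redoxmir.preprocess import trim_adapter
from redoxmir.sequences import dna, revcomp
from redoxmir.synthetic import (
    make_contaminants, make_genome, make_profile, simulate_reads,
    simulate_targets, TreatmentProfile,
)
from redoxmir.targets import scan_transcript
from redoxmir.keygene import pearson_r


class TestMakeGenome:
    def test_no_hairpins_gives_pure_random_genome(self):
        genome, truth = make_genome(1, 5000, 0, seed=0)
        assert truth.hairpins == [] and len(genome[0].seq) == 5000

    def test_positions_increasing_and_spaced(self):
        genome, truth = make_genome(2, 20000, 20, seed=1)
        assert len(truth.hairpins) == 20
        by_chrom = {}
        for hp in truth.hairpins:
            by_chrom.setdefault(hp.chrom, []).append(hp)
        for hps in by_chrom.values():
            starts = [h.start for h in hps]
            assert starts == sorted(starts)
            for a, b in zip(hps, hps[1:]):
                assert b.start - a.end >= 300

    def test_hairpin_reconstructs_contiguously_at_genome_pos(self):
        genome, truth = make_genome(1, 20000, 5, seed=2)
        gseq = {g.id: dna(g.seq) for g in genome}
        for hp in truth.hairpins:
            piece = gseq[hp.chrom][hp.start : hp.end]
            expected = hp.hairpin_seq if hp.strand == "+" else revcomp(hp.hairpin_seq)
            assert piece == dna(expected)

    def test_same_seed_identical(self):
        g1, t1 = make_genome(2, 10000, 6, seed=3)
        g2, t2 = make_genome(2, 10000, 6, seed=3)
        assert [r.seq for r in g1] == [r.seq for r in g2]
        assert [h.mature_seq for h in t1.hairpins] == [h.mature_seq for h in t2.hairpins]

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            make_genome(1, 1000, 10, seed=4)


class TestSimulateReads:
    @staticmethod
    def _setup(seed=5, n_hairpins=4, noise=0.0, depth=400, **kw):
        genome, truth = make_genome(1, 10000, n_hairpins, seed=seed)
        profile = make_profile(truth, seed=seed + 1)
        libs = simulate_reads(genome, truth, profile, total_depth=depth,
                              adapter=DEFAULT_ADAPTER, noise=noise,
                              seed=seed + 2, **kw)
        return genome, truth, profile, libs

    def test_noiseless_reads_all_inside_mature_windows(self):
        genome, truth, _, libs = self._setup(star_fraction=0.0)
        gseq = dna(genome[0].seq)
        mature_inserts = set()
        for hp in truth.hairpins:
            a, b = hp.mature_interval
            s = gseq[a:b]
            mature_inserts.add(s if hp.strand == "+" else revcomp(s))
        for records in libs.values():
            for r in records:
                insert, trimmed = trim_adapter(r.seq, DEFAULT_ADAPTER)
                assert trimmed and insert in mature_inserts

    def test_same_seed_identical_libraries(self):
        _, _, _, libs1 = self._setup()
        _, _, _, libs2 = self._setup()
        for lab in libs1:
            assert [r.seq for r in libs1[lab]] == [r.seq for r in libs2[lab]]

    def test_read_lengths_and_mature_lengths_pass_filters(self):
        genome, truth, _, libs = self._setup(noise=0.5, depth=600)
        for hp in truth.hairpins:
            assert 20 <= len(hp.mature_seq) <= 24
        for records in libs.values():
            for r in records:
                insert, trimmed = trim_adapter(r.seq, DEFAULT_ADAPTER)
                if trimmed:  # arm or degradation fragment
                    assert 18 <= len(insert) <= 30

    def test_planted_fold_change_recovered_at_depth(self):
        # one hairpin, 4x NaCl vs control, deep libraries
        genome, truth = make_genome(1, 8000, 1, seed=9)
        hp = truth.hairpins[0]
        profile = TreatmentProfile(
            replicates=2, means={hp.id: (1.0, 4.0, 1.0, 1.0)}, dispersion=1e6)
        libs = simulate_reads(genome, truth, profile, total_depth=10**4,
                              adapter=DEFAULT_ADAPTER, noise=0.0, seed=10)
        n_control = sum(len(libs[f"control_rep{i}"]) for i in (1, 2))
        n_nacl = sum(len(libs[f"NaCl_rep{i}"]) for i in (1, 2))
        assert np.log2(n_nacl / n_control) == pytest.approx(2.0, abs=0.3)

    def test_contaminant_reads_present_when_noisy(self):
        cont = make_contaminants(seed=0)
        genome, truth = make_genome(1, 10000, 2, seed=11)
        profile = make_profile(truth, seed=12)
        libs = simulate_reads(genome, truth, profile, total_depth=2000,
                              adapter=DEFAULT_ADAPTER, noise=0.5, seed=13,
                              contaminants=cont)
        cont_seqs = [dna(c.seq) for c in cont]
        found = False
        for records in libs.values():
            for r in records:
                insert, _ = trim_adapter(r.seq, DEFAULT_ADAPTER)
                if any(insert in c for c in cont_seqs):
                    found = True
        assert found


class TestSimulateTargets:
    @staticmethod
    def _run(noise=0.0, seed=20, n=8):
        genome, truth = make_genome(1, 20000, n, seed=seed)
        profile = make_profile(truth, seed=seed + 1)
        tx, m_prof, t_prof = simulate_targets(truth, profile, seed=seed + 2,
                                              noise=noise)
        return truth, profile, tx, {p.entity_id: p for p in m_prof}, \
            {p.entity_id: p for p in t_prof}

    def test_noiseless_inverse_pairs_have_r_minus_one(self):
        truth, _, _, m_prof, t_prof = self._run()
        checked = 0
        for mid, plan in truth.target_map.items():
            if plan.coupling == "inverse":
                r = pearson_r(m_prof[mid].values, t_prof[plan.transcript_id].values)
                if r is None:  # flat miRNA pattern: correctly indeterminate
                    continue
                assert r == pytest.approx(-1.0, abs=1e-12)
                checked += 1
        assert checked > 0

    def test_noiseless_decoupled_pairs_have_r_plus_one(self):
        truth, _, _, m_prof, t_prof = self._run(n=10)
        checked = 0
        for mid, plan in truth.target_map.items():
            if plan.coupling == "decoupled":
                r = pearson_r(m_prof[mid].values, t_prof[plan.transcript_id].values)
                assert r == pytest.approx(1.0, abs=1e-12)
                checked += 1
        assert checked > 0

    def test_planted_sites_scan_at_or_under_cutoff(self):
        truth, _, tx, _, _ = self._run()
        seqs = {t.id: t.seq for t in tx}
        for mid, plan in truth.target_map.items():
            hp = next(h for h in truth.hairpins if h.id == mid)
            sites = scan_transcript(hp.mature_seq, plan.transcript_id,
                                    seqs[plan.transcript_id])
            assert sites, f"planted site for {mid} not found"
            best = sites[0]
            assert best.site_start == plan.site_start
            assert best.expectation <= 2.0
            assert best.mode == plan.mode

    def test_key_gene_ids_populated(self):
        truth, _, _, _, _ = self._run()
        assert len(truth.key_gene_ids) == 2
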