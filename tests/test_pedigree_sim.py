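import numpy as np
import pytest

from ancestrybench._rng import substream
from ancestrybench.genotype_io import MISSING, GenotypeMatrix, MetadataError
from ancestrybench.pedigree_sim import (
    CohortBalanceError,
    Individual,
    Pedigree,
    PedigreeIntegrityError,
    SimConfig,
    block_bounds,
    founders_from_genotypes,
    impute_missing,
    make_gamete,
    mate,
    pedigree_genotypes,
    phase_founders,
    run_benchmark_sim,
)
from ancestrybench.synthetic_data import (
    generate_founders,
    random_admixture_vectors,
    sample_ancestral_frequencies,
)

from .conftest import make_founder_meta, make_markers


def make_founder_set(n=30, L=60, seed=0, K=2):
    F = sample_ancestral_frequencies(K=K, L=L, fst=0.2, seed=seed)
    qs = random_admixture_vectors(n, K, seed=seed)
    G, _, meta = generate_founders(F, qs, seed=seed)
    return G, meta


class TestBlocks:
    def test_three_blocks(self):
        blocks = block_bounds(make_markers(30_000), 10_000)
        assert blocks == [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]

    def test_ragged_tail(self):
        assert block_bounds(make_markers(25), 10) == [(0, 10), (10, 20), (20, 25)]

    def test_restart_at_chromosome_boundary(self):
        markers = make_markers(15, "1") + [
            m.__class__(chromosome="2", marker_id=f"c2_{i}", position=i + 1)
            for i, m in enumerate(make_markers(7))
        ]
        assert block_bounds(markers, 10) == [(0, 10), (10, 15), (15, 22)]

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            block_bounds(make_markers(5), 0)


class TestPhasing:
    def test_homozygous_unique(self):
        G = GenotypeMatrix(
            samples=["s"], markers=make_markers(4),
            dosages=np.array([[0, 2, 2, 0]]),
        )
        haps = phase_founders(G, seed=0)
        np.testing.assert_array_equal(haps[0, 0], [0, 1, 1, 0])
        np.testing.assert_array_equal(haps[0, 1], [0, 1, 1, 0])

    def test_sums_reproduce_dosages(self):
        G, _ = make_founder_set(10, 80, seed=1)
        haps = phase_founders(G, seed=1)
        np.testing.assert_array_equal(haps.sum(axis=1), G.dosages)

    def test_seed_determines_phase(self):
        G, _ = make_founder_set(10, 400, seed=2)
        h1 = phase_founders(G, seed=7)
        h2 = phase_founders(G, seed=7)
        np.testing.assert_array_equal(h1, h2)
        h3 = phase_founders(G, seed=8)
        het = G.dosages == 1
        diff = (h1[:, 0, :] != h3[:, 0, :])[het]
        # different seeds re-flip ~50% of het cells (3 SE binomial band)
        m = het.sum()
        assert abs(diff.mean() - 0.5) < 3 * np.sqrt(0.25 / m)

    def test_missing_rejected(self):
        G = GenotypeMatrix(
            samples=["s"], markers=make_markers(2),
            dosages=np.array([[MISSING, 1]]),
        )
        with pytest.raises(ValueError, match="imputed"):
            phase_founders(G, seed=0)

    def test_impute_missing(self):
        dosages = np.array([[MISSING, 1], [2, MISSING], [2, 0]])
        out = impute_missing(dosages, seed=0)
        assert (out != MISSING).all()
        assert out[0, 1] == 1 and out[2, 0] == 2  # observed cells untouched
        assert out[0, 0] in (0, 1, 2)


class TestGametes:
    def _parent(self, haps):
        return Individual(
            id="p", sex="female", generation=0,
            haplotypes=np.asarray(haps, dtype=np.int16),
            founder_label="labeled",
        )

    def test_homozygous_parent(self):
        hap = np.array([0, 1, 1, 0, 1])
        parent = self._parent([hap, hap])
        g = make_gamete(parent, [(0, 5)], substream(0, "t"))
        np.testing.assert_array_equal(g, hap)

    def test_every_block_matches_a_parental_block(self):
        rng0 = np.random.default_rng(0)
        parent = self._parent(rng0.integers(0, 2, size=(2, 47)))
        blocks = block_bounds(make_markers(47), 9)
        rng = substream(1, "gametes")
        for _ in range(50):
            g = make_gamete(parent, blocks, rng)
            for s, e in blocks:
                assert (
                    np.array_equal(g[s:e], parent.haplotypes[0, s:e])
                    or np.array_equal(g[s:e], parent.haplotypes[1, s:e])
                )

    def test_per_block_choice_is_fair(self):
        # 3 blocks of 10; parental haplotypes differ everywhere
        h0 = np.zeros(30, dtype=np.int16)
        h1 = np.ones(30, dtype=np.int16)
        parent = self._parent([h0, h1])
        blocks = block_bounds(make_markers(30), 10)
        rng = substream(2, "fairness")
        n = 10_000
        picks = np.zeros(3)
        for _ in range(n):
            g = make_gamete(parent, blocks, rng)
            for b, (s, e) in enumerate(blocks):
                picks[b] += g[s] == 1
        freq = picks / n
        assert (np.abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)).all()


class TestMate:
    def _ind(self, iid, sex, haps, label="labeled"):
        return Individual(
            id=iid, sex=sex, generation=0,
            haplotypes=np.asarray(haps, dtype=np.int16), founder_label=label,
        )

    def test_identical_homozygous_parents(self):
        hap = np.array([1, 0, 1, 1])
        mo = self._ind("m", "female", [hap, hap])
        fa = self._ind("f", "male", [hap, hap])
        kids = mate(mo, fa, 4, [(0, 4)], substream(0, "m"), 1, "P1")
        assert len(kids) == 4
        for kid in kids:
            np.testing.assert_array_equal(kid.dosages, 2 * hap)
            assert kid.mother_id == "m" and kid.father_id == "f"
            assert kid.generation == 1

    def test_mendelian_allele_containment(self):
        rng0 = np.random.default_rng(3)
        mo = self._ind("m", "female", rng0.integers(0, 2, (2, 40)))
        fa = self._ind("f", "male", rng0.integers(0, 2, (2, 40)))
        blocks = block_bounds(make_markers(40), 7)
        kids = mate(mo, fa, 10, blocks, substream(3, "m"), 1, "P1")
        for kid in kids:
            for l in range(40):
                assert kid.haplotypes[0, l] in mo.haplotypes[:, l]
                assert kid.haplotypes[1, l] in fa.haplotypes[:, l]

    def test_same_sex_pair_rejected(self):
        a = self._ind("a", "male", np.zeros((2, 3)))
        b = self._ind("b", "male", np.zeros((2, 3)))
        with pytest.raises(PedigreeIntegrityError):
            mate(a, b, 2, [(0, 3)], substream(0, "x"), 1, "P")

    def test_sex_ratio_binomial(self):
        hap = np.zeros(5, dtype=np.int16)
        mo = self._ind("m", "female", [hap, hap])
        fa = self._ind("f", "male", [hap, hap])
        rng = substream(4, "sexes")
        reps = 500
        females = sum(
            k.sex == "female"
            for _ in range(reps)
            for k in mate(mo, fa, 4, [(0, 5)], rng, 1, "P")
        )
        n = 4 * reps
        assert abs(females / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestRunBenchmarkSim:
    def test_default_counts(self):
        G, meta = make_founder_set(30, 60, seed=5)
        founders = founders_from_genotypes(G, meta, seed=5)
        cfg = SimConfig(hotspot_spacing=20, seed=5)
        ped = run_benchmark_sim(founders, cfg, G.markers)
        assert len(ped.generation_members(0)) == 30
        assert len(ped.generation_members(1)) == 60  # 15 pairs x 4
        assert len(ped.generation_members(2)) == 60
        assert len(ped) == 150

    def test_zero_generations(self):
        G, meta = make_founder_set(10, 20, seed=6)
        founders = founders_from_genotypes(G, meta, seed=6)
        cfg = SimConfig(
            n_founders=10, generations=0, cohort_size_per_generation=10,
            hotspot_spacing=5, seed=6,
        )
        ped = run_benchmark_sim(founders, cfg, G.markers)
        assert len(ped) == 10
        assert all(m.is_founder for m in ped.members.values())

    def test_parents_in_previous_generation(self):
        G, meta = make_founder_set(30, 40, seed=7)
        founders = founders_from_genotypes(G, meta, seed=7)
        ped = run_benchmark_sim(
            founders, SimConfig(hotspot_spacing=10, seed=7), G.markers
        )
        for m in ped.members.values():
            if not m.is_founder:
                assert ped[m.mother_id].generation == m.generation - 1
                assert ped[m.father_id].generation == m.generation - 1

    def test_reproducible(self):
        G, meta = make_founder_set(30, 40, seed=8)
        founders1 = founders_from_genotypes(G, meta, seed=8)
        founders2 = founders_from_genotypes(G, meta, seed=8)
        cfg = SimConfig(hotspot_spacing=10, seed=8)
        p1 = run_benchmark_sim(founders1, cfg, G.markers)
        p2 = run_benchmark_sim(founders2, cfg, G.markers)
        assert list(p1.members) == list(p2.members)
        for iid in p1.members:
            np.testing.assert_array_equal(
                p1[iid].haplotypes, p2[iid].haplotypes
            )
            assert p1[iid].sex == p2[iid].sex

    def test_unbalanced_founders_rejected(self):
        G, meta = make_founder_set(10, 20, seed=9)
        meta = [m.__class__(m.sample_id, "male", m.label, m.population) for m in meta]
        founders = founders_from_genotypes(G, meta, seed=9)
        cfg = SimConfig(
            n_founders=10, cohort_size_per_generation=10, hotspot_spacing=5, seed=9
        )
        with pytest.raises(CohortBalanceError):
            run_benchmark_sim(founders, cfg, G.markers)

    def test_unsexed_founder_rejected(self):
        G, meta = make_founder_set(4, 10, seed=10)
        meta[0] = meta[0].__class__(meta[0].sample_id, "unknown", "labeled", "")
        with pytest.raises(MetadataError):
            founders_from_genotypes(G, meta, seed=10)

    def test_drift_mean_zero_over_replicates(self):
        # pooled frequency change founders -> terminal has mean ~0 (paired
        # over seeds, markers subsampled; scaled down for runtime)
        G, meta = make_founder_set(30, 60, seed=11)
        founders = founders_from_genotypes(G, meta, seed=11)
        marker_idx = np.arange(0, 60, 3)
        f0 = G.dosages[:, marker_idx].mean(axis=0) / 2
        deltas = []
        for s in range(200):
            cfg = SimConfig(hotspot_spacing=20, seed=1000 + s)
            ped = run_benchmark_sim(founders, cfg, G.markers)
            Gt = pedigree_genotypes(ped)
            ft = Gt.dosages[:, marker_idx].mean(axis=0) / 2
            deltas.append((ft - f0).mean())
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_founders=31)
        with pytest.raises(ValueError):
            SimConfig(hotspot_spacing=0)
        with pytest.raises(ValueError):
            SimConfig(cohort_size_per_generation=31)
        with pytest.raises(ValueError):
            SimConfig(n_founders=4, cohort_size_per_generation=30)


class TestPedigreeStructure:
    def test_duplicate_id_rejected(self):
        ped = Pedigree()
        ind = Individual(
            id="x", sex="male", generation=0,
            haplotypes=np.zeros((2, 1)), founder_label="labeled",
        )
        ped.add(ind)
        with pytest.raises(PedigreeIntegrityError):
            ped.add(ind)

    def test_founder_without_label_rejected(self):
        ped = Pedigree()
        with pytest.raises(PedigreeIntegrityError):
            ped.add(Individual(id="x", sex="male", generation=0))

    def test_parent_sex_checked(self):
        ped = Pedigree()
        ped.add(Individual(id="a", sex="male", generation=0,
                           founder_label="labeled"))
        ped.add(Individual(id="b", sex="male", generation=0,
                           founder_label="labeled"))
        with pytest.raises(PedigreeIntegrityError, match="sex"):
            ped.add(Individual(id="c", sex="male", generation=1,
                               mother_id="a", father_id="b"))

    def test_to_table(self, tmp_path):
        G, meta = make_founder_set(4, 10, seed=12)
        founders = founders_from_genotypes(G, meta, seed=12)
        cfg = SimConfig(
            n_founders=4, cohort_size_per_generation=4, generations=1,
            hotspot_spacing=5, seed=12,
        )
        ped = run_benchmark_sim(founders, cfg, G.markers)
        ped.to_table(tmp_path / "ped.tsv")
        lines = (tmp_path / "ped.tsv").read_text().splitlines()
        assert lines[0].split("\t") == [
            "id", "sex", "mother", "father", "generation", "founder_label"
        ]
        assert len(lines) == 1 + len(ped)
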