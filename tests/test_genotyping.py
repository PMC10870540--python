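import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nataldisp.genotyping import (LocusDef, MultilocusGenotype, calibrate_datasets,
                                  match_pair, pid_combined, pid_locus,
                                  pid_sib_locus, screen)
from nataldisp.simulate import SimConfig, simulate_genotypes


# ---------------------------------------------------------------------------
# probability-of-identity oracles (exhaustive enumeration under HWE)


def hwe_genotype_distribution(freqs):
    """All unordered genotypes with their Hardy-Weinberg probabilities."""
    alleles = list(range(len(freqs)))
    out = {}
    for i in alleles:
        for j in alleles[i:]:
            p = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
            out[(i, j)] = p
    return out


def pid_enumeration(freqs):
    """P(two independent HWE draws identical) = sum_g P(g)^2."""
    return sum(p ** 2 for p in hwe_genotype_distribution(freqs).values())


def pid_sib_enumeration(freqs):
    """P(two full sibs identical): enumerate parental genotype pairs and the
    conditional offspring distribution."""
    gd = hwe_genotype_distribution(freqs)
    total = 0.0
    for gm, pm in gd.items():
        for gf, pf in gd.items():
            off = {}
            for am in gm:
                for af in gf:
                    g = (am, af) if am <= af else (af, am)
                    off[g] = off.get(g, 0.0) + 0.25
            total += pm * pf * sum(q ** 2 for q in off.values())
    return total


def _grid_configs():
    cfgs = [
        [0.5, 0.5],
        [0.9, 0.1],
        [1 / 3] * 3,
        [0.6, 0.3, 0.1],
        [0.25] * 4,
        [0.4, 0.3, 0.2, 0.1],
        [0.2] * 5,
        [0.35, 0.25, 0.2, 0.15, 0.05],
        [1 / 6] * 6,
        [0.3, 0.2, 0.2, 0.15, 0.1, 0.05],
    ]
    return cfgs


class TestProbabilityOfIdentity:
    def test_single_allele_is_certain_identity(self):
        locus = LocusDef("L", {150: 1.0})
        assert pid_locus(locus) == 1.0
        assert pid_sib_locus(locus) == 1.0

    def test_two_equifrequent_alleles(self):
        locus = LocusDef("L", {150: 0.5, 152: 0.5})
        assert pid_locus(locus) == pytest.approx(0.375, abs=1e-12)
        assert pid_sib_locus(locus) == pytest.approx(0.59375, abs=1e-12)

    @pytest.mark.parametrize("freqs", _grid_configs())
    def test_formulas_match_enumeration(self, freqs):
        sizes = [100 + 2 * i for i in range(len(freqs))]
        locus = LocusDef("L", dict(zip(sizes, freqs)))
        assert pid_locus(locus) == pytest.approx(pid_enumeration(freqs), abs=1e-12)
        assert pid_sib_locus(locus) == pytest.approx(pid_sib_enumeration(freqs), abs=1e-12)

    def test_combined_is_product_and_monotone(self):
        l1 = LocusDef("A", {1: 0.5, 2: 0.5})
        l2 = LocusDef("B", {1: 0.5, 2: 0.5})
        assert pid_combined([l1, l2]) == pytest.approx(0.140625, abs=1e-12)
        # adding an uninformative locus changes nothing
        l3 = LocusDef("C", {1: 1.0})
        assert pid_combined([l1, l2, l3]) == pid_combined([l1, l2])
        # combined never exceeds the smallest per-locus value
        assert pid_combined([l1, l2]) <= min(pid_locus(l1), pid_locus(l2))
        with pytest.raises(ValueError):
            pid_combined([])

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LocusDef("L", {1: 0.5, 2: 0.4})

    def test_fourteen_loci_five_alleles_identity_power(self):
        loci = [LocusDef(f"L{i}", {100 + 2 * a: 0.2 for a in range(5)})
                for i in range(14)]
        assert pid_combined(loci) < 1e-10


# ---------------------------------------------------------------------------
# pairwise matching


def _geno(sample_id, calls, sex="UNKNOWN"):
    return MultilocusGenotype(sample_id, calls, sex)


PANEL = [f"L{i}" for i in range(14)]


def _full_calls(pair=(150, 152)):
    return {l: pair for l in PANEL}


class TestMatchPair:
    def test_identical_genotypes_match(self):
        a = _geno("a", _full_calls())
        r = match_pair(a, _geno("b", _full_calls()))
        assert (r.decision, r.n_compared, r.n_mismatch) == ("MATCH", 14, 0)

    def test_missing_locus_is_wildcard(self):
        calls = _full_calls()
        calls["L0"] = None
        r = match_pair(_geno("a", calls), _geno("b", _full_calls()))
        assert r.decision == "MATCH"
        assert r.n_compared == 13

    def test_single_allele_difference_rejects(self):
        other = _full_calls()
        other["L0"] = (150, 154)
        r = match_pair(_geno("a", _full_calls()), _geno("b", other))
        assert r.decision == "NO_MATCH"
        assert r.n_mismatch == 1

    def test_homozygote_heterozygote_is_full_mismatch(self):
        other = _full_calls()
        other["L0"] = (150, 150)
        r = match_pair(_geno("a", _full_calls()), _geno("b", other))
        assert r.n_mismatch == 1

    def test_insufficient_overlap(self):
        few = {l: (150, 152) for l in PANEL[:8]}
        rest = {l: None for l in PANEL[8:]}
        r = match_pair(_geno("a", {**few, **rest}), _geno("b", _full_calls()))
        assert r.decision == "INSUFFICIENT_OVERLAP"

    def test_disjoint_panels_rejected(self):
        with pytest.raises(ValueError):
            match_pair(_geno("a", {"L0": (1, 2)}), _geno("b", {"L9": (1, 2)}))

    @given(st.lists(st.sampled_from([None, (150, 152), (150, 154), (152, 152)]),
                    min_size=14, max_size=14),
           st.lists(st.sampled_from([None, (150, 152), (150, 154), (152, 152)]),
                    min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_arguments(self, calls_a, calls_b):
        a = _geno("a", dict(zip(PANEL, calls_a)))
        b = _geno("b", dict(zip(PANEL, calls_b)))
        ra = match_pair(a, b, min_overlap=1)
        rb = match_pair(b, a, min_overlap=1)
        assert (ra.n_compared, ra.n_mismatch, ra.decision) == \
               (rb.n_compared, rb.n_mismatch, rb.decision)

    def test_equal_locus_removal_never_flips_match(self):
        a = _geno("a", _full_calls())
        b = _geno("b", _full_calls())
        assert match_pair(a, b).decision == "MATCH"
        calls = _full_calls()
        calls.pop("L13")
        a2 = _geno("a", calls)
        r = match_pair(a2, b, min_overlap=9)
        assert r.decision == "MATCH"


# ---------------------------------------------------------------------------
# table-level screening


def _sim_tables(seed, n_ind=30, missing=0.1):
    """Small synthetic panel: nestlings + adult re-observations of a subset."""
    cfg = SimConfig(seed=seed, missing_locus_prob=missing)
    rng = cfg.rng()
    nest = pd.DataFrame({
        "individual_id": [f"W{i:03d}" for i in range(n_ind)],
        "territory_id": [f"T{i % 10}" for i in range(n_ind)],
        "nest_id": "n", "lat": 60.0, "lon": 25.0,
        "hatch_year": 2005, "sex": ["F", "M"] * (n_ind // 2),
    })
    adults = pd.DataFrame({
        "individual_id": [f"W{i:03d}" for i in range(0, n_ind, 2)],
        "territory_id": "TB", "year": 2012,
    })
    g, truth = simulate_genotypes(nest, {}, cfg, rng,
                                  nestling_sample_ids=nest["individual_id"].tolist(),
                                  adult_samples=adults)
    return g, set(adults["individual_id"])


class TestScreen:
    def test_true_links_recovered_no_false_links(self):
        g, true_adults = _sim_tables(seed=7)
        matches, report = screen(g[g["type"] == "nestling"],
                                 g[g["type"] == "adult"])
        linked = dict(zip(matches["adult_sample"], matches["nestling_individual"]))
        for a, ind in linked.items():
            assert a == f"A-{ind}-2012"  # every link is the true individual
        assert not matches["ambiguous"].any()

    def test_low_locus_samples_dropped(self):
        g, _ = _sim_tables(seed=3)
        g = g.copy()
        # knock a nestling sample down to 8 typed loci
        loci = [c[:-3] for c in g.columns if c.endswith("_a1")]
        victim = g.index[g["type"] == "nestling"][0]
        for locus in loci[:6]:
            g.loc[victim, [f"{locus}_a1", f"{locus}_a2"]] = np.nan
        sid = g.loc[victim, "sample_id"]
        matches, report = screen(g[g["type"] == "nestling"], g[g["type"] == "adult"])
        assert sid not in set(matches["nestling_sample"])

    def test_adult_matching_two_individuals_flagged_ambiguous(self):
        loci = [f"L{i}" for i in range(10)]
        def row(sid, stype, ind):
            r = {"sample_id": sid, "type": stype, "year": 2010,
                 "territory_id": "T", "individual_id": ind, "sex_marker": "F"}
            for l in loci:
                r[f"{l}_a1"], r[f"{l}_a2"] = 150, 152
            return r
        nest = pd.DataFrame([row("n1", "nestling", "W1"), row("n2", "nestling", "W2")])
        adults = pd.DataFrame([row("a1", "adult", "")])
        matches, report = screen(nest, adults)
        assert matches["ambiguous"].all()
        assert report["status"].iloc[0] == "AMBIGUOUS"

    def test_empty_inputs_yield_empty_results(self):
        empty = pd.DataFrame(columns=["sample_id", "L0_a1", "L0_a2"])
        matches, report = screen(empty, empty)
        assert matches.empty and report.empty


# ---------------------------------------------------------------------------
# cross-laboratory calibration


def _ref_frames(shifts):
    """Reference individuals typed in two labs; old lab shifted by `shifts`
    at locus L0 (one entry per individual)."""
    loci = ["L0", "L1"]
    rows_new, rows_old = [], []
    for i, s in enumerate(shifts):
        new = {"individual_id": f"R{i}", "sample_id": f"new{i}"}
        old = {"individual_id": f"R{i}", "sample_id": f"old{i}"}
        for l in loci:
            a = 150 + 2 * i
            new[f"{l}_a1"], new[f"{l}_a2"] = a, a + 2
            off = s if l == "L0" else 0
            old[f"{l}_a1"], old[f"{l}_a2"] = a - off, a + 2 - off
        rows_new.append(new)
        rows_old.append(old)
    return pd.DataFrame(rows_new), pd.DataFrame(rows_old)


class TestCalibration:
    def test_identical_reference_pairs_give_zero_offsets(self):
        new, old = _ref_frames([0, 0, 0])
        calibrated, report = calibrate_datasets(new, old, old.copy())
        assert (report["offset"] == 0).all()
        assert (report["status"] == "OK").all()
        pd.testing.assert_frame_equal(calibrated, old)

    def test_systematic_shift_detected_and_applied(self):
        new, old = _ref_frames([2, 2, 2])
        calibrated, report = calibrate_datasets(new, old, old.copy())
        r0 = report.set_index("locus").loc["L0"]
        assert r0["offset"] == 2
        assert r0["concordance"] == 1.0
        assert (calibrated["L0_a1"] == old["L0_a1"] + 2).all()

    def test_mode_offset_with_residual_discordance(self):
        new, old = _ref_frames([2, 2, 4])
        calibrated, report = calibrate_datasets(new, old, old.copy(),
                                                max_discordance=0.5)
        r0 = report.set_index("locus").loc["L0"]
        assert r0["offset"] == 2
        assert r0["n_discordant"] == 1
        assert r0["status"] == "OK"

    def test_uncalibratable_locus_masked(self):
        new, old = _ref_frames([2, 4, 6])   # no consistent shift
        calibrated, report = calibrate_datasets(new, old, old.copy(),
                                                max_discordance=0.1)
        r0 = report.set_index("locus").loc["L0"]
        assert r0["status"] == "UNCALIBRATED"
        assert calibrated["L0_a1"].isna().all()

    def test_no_shared_individuals_rejected(self):
        new, old = _ref_frames([0])
        old["individual_id"] = "X0"
        with pytest.raises(ValueError):
            calibrate_datasets(new, old, old.copy())
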