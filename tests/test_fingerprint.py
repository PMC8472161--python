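import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepfinger.fingerprint import (
    FingerprintError,
    additivity_defect,
    build_fingerprints,
    enrichment,
    fingerprint_sample,
    fingerprint_table,
    inhibition_profile,
    mp_csc_ratio,
    relative_contributions,
)
from pepfinger.plate_io import SUBSTRATES


class TestRelativeContributions:
    def test_uniform_and_single(self):
        np.testing.assert_allclose(relative_contributions([1] * 5), [20] * 5)
        np.testing.assert_allclose(
            relative_contributions([100, 0, 0, 0, 0]), [100, 0, 0, 0, 0]
        )

    def test_published_mean_vector(self):
        """Arithmetic on the reported per-substrate mean Vmax values: the PepC
        share of the pooled panel is 100 * 2140.7 / 4740.3."""
        v = [552.7, 465.1, 2140.7, 335.5, 1246.3]
        out = relative_contributions(v)
        assert out[2] == pytest.approx(100 * 2140.7 / sum(v), rel=1e-12)

    def test_all_zero_returns_zero(self):
        np.testing.assert_array_equal(relative_contributions([0] * 5), [0] * 5)

    def test_negative_entry_rejected(self):
        with pytest.raises(FingerprintError):
            relative_contributions([1, -1, 0, 0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False), min_size=5, max_size=5),
        st.permutations(range(5)),
    )
    def test_sums_to_100_and_permutation_equivariant(self, v, perm):
        out = relative_contributions(v)
        if sum(v) > 0:
            assert out.sum() == pytest.approx(100.0, abs=1e-6)
        permuted = relative_contributions([v[i] for i in perm])
        np.testing.assert_allclose(permuted, out[list(perm)], atol=1e-9)


class TestInhibitionProfile:
    def test_identity_full_and_disinhibited(self):
        assert inhibition_profile(100, 100) == (100.0, 0.0, False)
        assert inhibition_profile(100, 0) == (0.0, 100.0, False)
        res, inh, dis = inhibition_profile(100, 102.5)
        # residual above 100% is the published disinhibition convention
        assert (res, inh, dis) == (102.5, -2.5, True)

    def test_zero_control_is_undefined(self):
        with pytest.raises(FingerprintError):
            inhibition_profile(0.0, 10.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1e-3, 1e4), st.floats(0, 10))
    def test_residual_plus_inhibition_is_exactly_100(self, none, factor):
        inhibited = none * factor
        res, inh, dis = inhibition_profile(none, inhibited)
        assert res + inh == pytest.approx(100.0, abs=1e-9)
        assert dis == (inhibited > none)


class TestRatiosAndAdditivity:
    def test_mp_csc_ratio(self):
        assert mp_csc_ratio(10, 10) == 1.0
        assert mp_csc_ratio(18, 10) == pytest.approx(1.8)
        assert math.isnan(mp_csc_ratio(10, 0))
        assert mp_csc_ratio(-5, 10) == 0.0  # disinhibited MP clamps to zero

    def test_additivity_defect_signs(self):
        # inhibitions: BOTHi 50, MMPi 30, COMi 20 -> +20 (additive)
        assert additivity_defect(100, 70, 80, 50) == pytest.approx(20.0)
        # BOTHi 25 below max(30, 20) -> -5 flags the sub-additive interaction
        assert additivity_defect(100, 70, 80, 75) == pytest.approx(-5.0)
        assert additivity_defect(100, 100, 100, 100) == pytest.approx(0.0)


def _vmax_map(rng):
    vmax = {}
    for s in SUBSTRATES:
        base = rng.uniform(50, 2000)
        vmax[(s, "NONE")] = base
        for g in ("MMPi", "COMi", "BOTHi"):
            vmax[(s, g)] = base * rng.uniform(0.3, 1.2)
    return vmax


class TestSampleFingerprint:
    def test_invariants_on_random_samples(self, rng):
        for _ in range(20):
            vmax = _vmax_map(rng)
            fp = fingerprint_sample("S", "saliva", vmax)
            assert sum(fp.rel_contrib.values()) == pytest.approx(100, abs=1e-6)
            for s in SUBSTRATES:
                for g in ("MMPi", "COMi", "BOTHi"):
                    assert fp.residual_pct[s][g] + fp.inhibition_pct[s][g] == pytest.approx(
                        100, abs=1e-9
                    )
                    assert fp.disinhibited[s][g] == (
                        vmax[(s, g)] > vmax[(s, "NONE")]
                    )
                    # signed contributions are preserved outside the ratio
                    assert fp.contribution_vmax[s][g] == pytest.approx(
                        vmax[(s, "NONE")] - vmax[(s, g)]
                    )

    def test_missing_uninhibited_well_rejected(self):
        with pytest.raises(FingerprintError, match="uninhibited"):
            fingerprint_sample("S", "saliva", {("PepA", "MMPi"): 1.0})

    def test_table_schema(self, rng):
        fp = fingerprint_sample("S", "saliva", _vmax_map(rng))
        table = fingerprint_table([fp])
        assert len(table) == 1
        for col in ("PepE_COMi_ABS_CONT", "PepA_MMPi_RES", "PepC_MPCSC", "TOTAL_ABS"):
            assert col in table.columns


class TestEnrichment:
    def _fp(self, sid, stype, scale):
        vmax = {(s, "NONE"): scale for s in SUBSTRATES}
        return fingerprint_sample(sid, stype, vmax)

    def test_published_dilution_factors_give_37_5(self):
        sal = self._fp("P1", "saliva", 100.0)
        bio = self._fp("P1", "biopsy", 100.0)
        rec = enrichment(sal, bio, saliva_dilution=20.0, biopsy_dilution=750.0)
        for s in SUBSTRATES:
            assert rec.enrichment_ratio[s] == pytest.approx(750.0 / 20.0)

    def test_identity_and_zero_saliva(self):
        sal = self._fp("P1", "saliva", 100.0)
        bio = self._fp("P1", "biopsy", 100.0)
        rec = enrichment(sal, bio, 20.0, 20.0)
        assert rec.enrichment_ratio["PepA"] == pytest.approx(1.0)
        zero = self._fp("P1", "saliva", 0.0)
        rec0 = enrichment(zero, bio, 20.0, 750.0)
        assert math.isnan(rec0.enrichment_ratio["PepA"])

    def test_sample_mismatch_rejected(self):
        with pytest.raises(FingerprintError):
            enrichment(
                self._fp("P1", "saliva", 1.0), self._fp("P2", "biopsy", 1.0), 20, 750
            )


def test_build_fingerprints_from_simulated_plate(small_cohort):
    """Well-level construction: every saliva/biopsy specimen in a simulated
    plate yields one fingerprint covering all substrates."""
    wells, truth = small_cohort
    fps = build_fingerprints(wells)
    assert len(fps) == len(truth)
    ids = {(fp.sample_id, fp.sample_type) for fp in fps}
    assert ("CAR001", "saliva") in ids
    for fp in fps:
        assert set(fp.abs_vmax) == set(SUBSTRATES)
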