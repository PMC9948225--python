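"""Similarity index, retention index, and RI-windowed library search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from terpscreen.identify import (
    UNKNOWN_COMPOUND,
    identify_products,
    retention_index,
    search_library,
    similarity_index,
)
from terpscreen.spectra import LibraryEntry, MassSpectrum, RetentionLadder, normalize_spectrum
from terpscreen.synth import make_ladder, make_library

from conftest import random_spectrum


def naive_si(u: MassSpectrum, t: MassSpectrum) -> float:
    """Independent per-m/z loop over the union support (the test oracle)."""
    u, t = normalize_spectrum(u), normalize_spectrum(t)
    du = dict(zip(u.mz.tolist(), u.intensities.tolist()))
    dt = dict(zip(t.mz.tolist(), t.intensities.tolist()))
    num = den = 0.0
    for mz in sorted(set(du) | set(dt)):
        iu, it = du.get(mz, 0.0), dt.get(mz, 0.0)
        num += abs(iu - it)
        den += iu + it
    return (1.0 - num / den) * 100.0


@st.composite
def spectra(draw):
    n = draw(st.integers(min_value=1, max_value=25))
    mz = draw(
        st.lists(st.integers(min_value=41, max_value=220), min_size=n, max_size=n, unique=True)
    )
    inten = draw(
        st.lists(
            st.floats(min_value=1e-3, max_value=1e3, allow_nan=False), min_size=n, max_size=n
        )
    )
    order = np.argsort(mz)
    return MassSpectrum(np.asarray(mz)[order], np.asarray(inten)[order])


class TestSimilarityIndex:
    def test_worked_example(self):
        u = MassSpectrum([41, 55], [100.0, 50.0])
        t = MassSpectrum([41, 55], [50.0, 100.0])
        # sum|diff| = 100, sum = 300 -> (1 - 1/3) * 100
        assert similarity_index(u, t) == pytest.approx(200.0 / 3.0, abs=1e-12)

    def test_self_match_is_exactly_100(self, rng):
        for _ in range(5):
            s = random_spectrum(rng)
            assert similarity_index(s, s) == 100.0

    def test_disjoint_supports_score_zero(self):
        a = MassSpectrum([41, 55], [100.0, 40.0])
        b = MassSpectrum([57, 91], [100.0, 10.0])
        assert similarity_index(a, b) == 0.0

    @given(spectra(), spectra())
    def test_symmetric_bounded_and_matches_oracle(self, a, b):
        si = similarity_index(a, b)
        assert similarity_index(b, a) == pytest.approx(si, abs=1e-12)
        assert 0.0 <= si <= 100.0
        assert si == pytest.approx(naive_si(a, b), abs=1e-9)
        if si == 0.0:
            assert not set(a.mz.tolist()) & set(b.mz.tolist())

    @given(spectra(), st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, s, c):
        scaled = MassSpectrum(s.mz, s.intensities * c)
        assert similarity_index(s, scaled) == pytest.approx(100.0, abs=1e-9)

    def test_rejects_invalid_spectrum(self):
        with pytest.raises(ValueError):
            MassSpectrum([], [])


class TestRetentionIndex:
    @pytest.fixture
    def ladder(self):
        return make_ladder()

    def test_exact_at_every_rung(self, ladder):
        for c, t in ladder.rungs:
            assert retention_index(t, ladder) == pytest.approx(100.0 * c, abs=1e-9)

    def test_midpoint_and_quarter_interpolation(self, ladder):
        times = dict(zip(ladder.carbon_numbers.tolist(), ladder.retention_times.tolist()))
        t13, t14 = times[13], times[14]
        assert retention_index((t13 + t14) / 2, ladder) == pytest.approx(1350.0)
        assert retention_index(t13 + 0.25 * (t14 - t13), ladder) == pytest.approx(1325.0)

    def test_strictly_monotone_in_rt(self, ladder, rng):
        lo, hi = ladder.span
        rts = np.sort(rng.uniform(lo, hi, size=100))
        ris = [retention_index(t, ladder) for t in rts]
        assert all(b > a for a, b in zip(ris, ris[1:]))

    def test_affine_retiming_leaves_ri_unchanged(self, ladder, rng):
        rt = 40.0
        ri = retention_index(rt, ladder)
        scaled = RetentionLadder(ladder.carbon_numbers, 1.7 * ladder.retention_times + 3.0)
        assert retention_index(1.7 * rt + 3.0, scaled) == pytest.approx(ri, abs=1e-9)

    @pytest.mark.parametrize("rt", [0.0, 1e6])
    def test_no_extrapolation(self, ladder, rt):
        with pytest.raises(ValueError, match="span"):
            retention_index(rt, ladder)


class TestSearchLibrary:
    @pytest.fixture
    def library(self):
        return make_library(20, seed=9)

    def test_identical_in_window_entry_is_rank1_si100(self, library):
        entry = library[0]
        hits = search_library(entry.spectrum, entry.reference_ri, library)
        assert hits[0].compound_name == entry.compound_name
        assert hits[0].si == 100.0
        assert hits[0].rank == 1

    def test_out_of_window_entries_never_scored(self, library, rng):
        q = random_spectrum(rng)
        hits = search_library(q, 5000.0, library, ri_window=15.0, min_si=0.0)
        assert hits == []
        for w in (0.0, 15.0, 100.0):
            for h in search_library(q, 1450.0, library, ri_window=w, min_si=0.0):
                assert abs(h.delta_ri) <= w

    def test_ranking_total_order(self, library, rng):
        q = random_spectrum(rng)
        hits = search_library(q, 1480.0, library, ri_window=200.0, min_si=0.0)
        assert [h.rank for h in hits] == list(range(1, len(hits) + 1))
        keys = [(-h.si, abs(h.delta_ri), h.compound_name) for h in hits]
        assert keys == sorted(keys)

    def test_shared_intensity_orders_hits(self):
        q = MassSpectrum([41, 55, 91], [100.0, 60.0, 30.0])
        close = LibraryEntry("close", MassSpectrum([41, 55, 91], [100.0, 55.0, 25.0]), 1400.0)
        far = LibraryEntry("far", MassSpectrum([41, 105, 161], [100.0, 80.0, 70.0]), 1400.0)
        hits = search_library(q, 1400.0, [close, far], min_si=0.0)
        assert [h.compound_name for h in hits] == ["close", "far"]
        assert hits[0].si > hits[1].si

    @pytest.mark.parametrize("kwargs", [{"ri_window": -1.0}, {"min_si": 101.0}, {"min_si": -5.0}])
    def test_invalid_arguments(self, library, rng, kwargs):
        with pytest.raises(ValueError):
            search_library(random_spectrum(rng), 1400.0, library, **kwargs)


class TestIdentifyProducts:
    def test_matching_queries_named_and_nonmatch_is_unknown(self, rng):
        library = make_library(10, seed=2)
        ladder = make_ladder()
        times = ladder.retention_times
        carbons = ladder.carbon_numbers.astype(float)
        queries = []
        for k in (0, 3, 7):
            e = library[k]
            rt = float(np.interp(e.reference_ri / 100.0, carbons, times))
            queries.append((f"STS-{k}", e.spectrum, rt))
        queries.append(("STS-x", random_spectrum(rng), float(times[10])))
        table = identify_products(queries, ladder, library)
        frame = table.to_dataframe()
        assert list(frame["compound"][:3]) == [library[k].compound_name for k in (0, 3, 7)]
        assert (frame["SI"][:3] == 100.0).all()
        last = frame.iloc[-1]
        assert last["compound"] == UNKNOWN_COMPOUND and last["SI"] == "ND"

    def test_deterministic_tsv_output(self, tmp_path, rng):
        library = make_library(5, seed=6)
        ladder = make_ladder()
        queries = [("e1", library[0].spectrum, 30.0), ("e2", random_spectrum(rng), 40.0)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        identify_products(queries, ladder, library).to_tsv(p1)
        identify_products(queries, ladder, library).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
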