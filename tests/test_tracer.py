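"""Tracer diagnostic-ion filtering and the modified-cosine network."""

import itertools
import math

import numpy as np
import pytest

from gsltracer.msio import FeatureRecord, FragmentPeak, Ms2Spectrum, read_feature_table, read_mgf
from gsltracer.simulate import synth_spectrum
from gsltracer.tracer import (
    SpectralNetwork,
    TracerRuleSet,
    build_network,
    export_gnps_bundle,
    modified_cosine,
    network_metrics,
    tracer_filter,
)


def spectrum(sid, precursor, peaks_ra):
    base = 1e5
    peaks = tuple(FragmentPeak(mz=mz, intensity=base * ra) for mz, ra in peaks_ra)
    return Ms2Spectrum(sid, precursor, rt_min=1.0, charge=-1, peaks=peaks).normalize()


GSL_PEAKS = [(96.9601, 0.95), (74.9872, 0.6), (259.0129, 0.1), (150.0, 1.0)]


def test_tracer_filter_retains_planted_gsl():
    spec = spectrum("g1", 436.0416, GSL_PEAKS)
    retained, _ = tracer_filter([spec], [], TracerRuleSet())
    assert [s.spectrum_id for s in retained] == ["g1"]


def test_tracer_filter_removes_sulfate_free_decoy():
    spec = spectrum("d1", 430.0, [(120.0, 1.0), (200.0, 0.5)])
    retained, _ = tracer_filter([spec], [], TracerRuleSet())
    assert retained == []


def test_tracer_filter_primary_below_threshold_removed():
    peaks = [(96.9601, 0.4), (74.9872, 0.6), (259.0129, 0.1), (150.0, 1.0)]
    retained, _ = tracer_filter([spectrum("g1", 436.0416, peaks)], [], TracerRuleSet())
    assert retained == []


def test_tracer_filter_secondary_gate_is_or():
    # no secondary ion at all -> removed; any one secondary -> retained
    no_secondary = [(96.9601, 0.95), (74.9872, 0.6), (150.0, 1.0)]
    retained, _ = tracer_filter([spectrum("s", 436.0, no_secondary)], [], TracerRuleSet())
    assert retained == []
    with_192 = no_secondary + [(192.0194, 0.05)]
    retained, _ = tracer_filter([spectrum("s", 436.0, with_192)], [], TracerRuleSet())
    assert len(retained) == 1


def test_tracer_filter_literal_windows_exclude_true_ions():
    # with widening disabled, the 2-decimal targets cannot capture HSO4-
    rules = TracerRuleSet(widen_primary=False)
    retained, _ = tracer_filter([spectrum("g1", 436.0416, GSL_PEAKS)], [], rules)
    assert retained == []


def test_tracer_filter_subset_and_idempotent(small_library, rng):
    spectra = [synth_spectrum(c, rng=rng) for c in small_library]
    features = [FeatureRecord(c.name, c.mz, 1.0) for c in small_library]
    once_s, once_f = tracer_filter(spectra, features, TracerRuleSet())
    twice_s, twice_f = tracer_filter(once_s, once_f, TracerRuleSet())
    assert {s.spectrum_id for s in once_s} <= {s.spectrum_id for s in spectra}
    assert [s.spectrum_id for s in twice_s] == [s.spectrum_id for s in once_s]
    assert [f.feature_id for f in once_f] == [s.spectrum_id for s in once_s]


def test_export_gnps_bundle_round_trip(tmp_path):
    spectra = [spectrum("g1", 436.0416, GSL_PEAKS), spectrum("g2", 422.0255, GSL_PEAKS)]
    features = [FeatureRecord("g1", 436.0416, 1.0, 5.0), FeatureRecord("g2", 422.0255, 1.5, 6.0)]
    mgf_path, csv_path = export_gnps_bundle(spectra, features, tmp_path / "out")
    back = read_mgf(mgf_path)
    feats = read_feature_table(csv_path)
    assert len(back) == len(feats) == 2
    assert [s.spectrum_id for s in back] == ["g1", "g2"]
    for a, b in zip(spectra, back):
        assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)


def test_export_empty_bundle(tmp_path):
    mgf_path, csv_path = export_gnps_bundle([], [], tmp_path / "out")
    assert read_mgf(mgf_path) == []
    assert csv_path.read_text().strip() == "id,mz,rt,area"


# ------------------------------------------------------------ modified cosine
def brute_force_modified_cosine(a, b, tol=0.01):
    """Exhaustive best one-to-one pairing over direct + shifted matches."""
    wa = [math.sqrt(p.intensity) for p in a.peaks]
    wb = [math.sqrt(p.intensity) for p in b.peaks]
    na = math.sqrt(sum(w * w for w in wa))
    nb = math.sqrt(sum(w * w for w in wb))
    shift = a.precursor_mz - b.precursor_mz
    allowed = {
        (i, j)
        for i, pa in enumerate(a.peaks)
        for j, pb in enumerate(b.peaks)
        if abs(pa.mz - pb.mz) <= tol or abs(pa.mz - pb.mz - shift) <= tol
    }
    best = 0.0
    n, m = len(a.peaks), len(b.peaks)
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                pairs = list(zip(rows, cols))
                if all(p in allowed for p in pairs):
                    best = max(best, sum(wa[i] * wb[j] for i, j in pairs))
    return best / (na * nb) if na and nb else 0.0


def test_identical_spectra_score_one():
    a = spectrum("a", 436.0, GSL_PEAKS)
    score, matched = modified_cosine(a, a)
    assert score == pytest.approx(1.0, abs=1e-9)
    assert matched == len(a.peaks)


def test_disjoint_spectra_score_zero():
    a = spectrum("a", 400.0, [(100.0, 1.0), (150.0, 0.5)])
    b = spectrum("b", 400.0, [(120.0, 1.0), (170.0, 0.5)])
    assert modified_cosine(a, b) == (0.0, 0)


def test_modified_cosine_symmetric_and_bounded(rng):
    for _ in range(10):
        a = spectrum("a", float(rng.uniform(350, 500)),
                     [(float(rng.uniform(80, 300)), float(rng.uniform(0.1, 1))) for _ in range(5)])
        b = spectrum("b", float(rng.uniform(350, 500)),
                     [(float(rng.uniform(80, 300)), float(rng.uniform(0.1, 1))) for _ in range(5)])
        s_ab, m_ab = modified_cosine(a, b)
        s_ba, m_ba = modified_cosine(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)
        assert m_ab == m_ba
        assert 0.0 <= s_ab <= 1.0


def test_modified_cosine_matches_brute_force(rng):
    """5-peak toys: Hungarian assignment equals exhaustive enumeration."""
    for trial in range(15):
        pa = float(rng.uniform(380, 420))
        pb = pa - float(rng.choice([0.0, 14.0157, 28.0313]))
        mzs = rng.uniform(80, 300, size=5)
        a = spectrum("a", pa, [(float(m), float(rng.uniform(0.1, 1))) for m in mzs])
        # b shares some peaks directly, some shifted by the precursor delta
        b_peaks = [(float(mzs[0]), 0.8), (float(mzs[1]) - (pa - pb), 0.6),
                   (float(rng.uniform(80, 300)), 0.5), (float(mzs[2]), 0.4),
                   (float(mzs[3]) - (pa - pb), 0.3)]
        b = spectrum("b", pb, [(max(m, 50.0), ra) for m, ra in b_peaks])
        score, _ = modified_cosine(a, b)
        assert score == pytest.approx(brute_force_modified_cosine(a, b), abs=1e-9)


def test_equal_precursors_reduce_to_classic_cosine(rng):
    shared = [(100.0, 0.9), (150.0, 0.4), (200.0, 1.0)]
    a = spectrum("a", 400.0, shared + [(250.0, 0.2)])
    b = spectrum("b", 400.0, shared + [(260.0, 0.3)])
    score, _ = modified_cosine(a, b)
    wa = np.sqrt([p.intensity for p in a.peaks])
    wb = np.sqrt([p.intensity for p in b.peaks])
    # classic cosine over the directly matching positions
    num = sum(
        math.sqrt(pa.intensity * pb.intensity)
        for pa in a.peaks
        for pb in b.peaks
        if abs(pa.mz - pb.mz) <= 0.01
    )
    assert score == pytest.approx(num / (np.linalg.norm(wa) * np.linalg.norm(wb)), abs=1e-9)


# ------------------------------------------------------------------- network
def test_build_network_identical_pair_edge():
    peaks = [(float(m), 0.5 + 0.05 * i) for i, m in enumerate((90, 110, 130, 150, 170, 190))]
    a = spectrum("a", 400.0, peaks)
    b = spectrum("b", 400.0, peaks)
    net = build_network([a, b], min_cosine=0.7, min_matched_peaks=6)
    assert set(net.nodes) == {"a", "b"}
    assert len(net.edges) == 1
    assert net.edges[0][2]["cosine"] == pytest.approx(1.0)


def test_build_network_min_matched_peaks_gate():
    peaks = [(90.0, 1.0), (110.0, 0.5)]
    a = spectrum("a", 400.0, peaks)
    b = spectrum("b", 400.0, peaks)
    net = build_network([a, b], min_cosine=0.5, min_matched_peaks=6)
    assert len(net.edges) == 0  # perfect score but only 2 matched peaks


def test_build_network_rejects_empty():
    with pytest.raises(ValueError):
        build_network([])


def test_top_k_caps_node_degree():
    peaks = [(float(m), 0.5) for m in (90, 110, 130, 150, 170, 190)]
    spectra = [spectrum(f"s{i}", 400.0, peaks) for i in range(6)]
    net = build_network(spectra, min_cosine=0.7, min_matched_peaks=6, top_k=2)
    degrees = dict(net.graph.degree())
    assert max(degrees.values()) <= 2


def test_network_metrics_hand_counts():
    net = SpectralNetwork()
    net.graph.add_nodes_from("abcd")
    net.graph.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    metrics = network_metrics(net, unfiltered_node_count=10)
    assert metrics["nodes"] == 4
    assert metrics["edges"] == 3
    assert metrics["connected_components"] == 2  # triangle + isolated d
    assert metrics["redundancy_reduction"] == pytest.approx(0.6)
    with pytest.raises(ValueError):
        network_metrics(net, unfiltered_node_count=3)


def test_tracer_network_pipeline_subset(small_library, rng):
    spectra = [synth_spectrum(c, rng=rng) for c in small_library]
    retained, _ = tracer_filter(spectra, [], TracerRuleSet())
    if retained:
        net = build_network(retained, min_cosine=0.5, min_matched_peaks=3)
        assert set(net.nodes) <= {s.spectrum_id for s in spectra}
        metrics = network_metrics(net, unfiltered_node_count=len(spectra))
        assert 0.0 <= metrics["redundancy_reduction"] <= 1.0
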