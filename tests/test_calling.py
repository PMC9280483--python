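import pytest

from msipeaks import (
    Hyperparameters,
    Peak,
    PeakSet,
    UncallableError,
    call_sample_pair,
    classify_patient,
    compare_marker,
)
from msipeaks.calling import MarkerCall
from msipeaks.simulate import write_fixture_bam


def peak_set(positions, marker="Bat25", tissue="tumor", total_reads=100):
    return PeakSet(
        sample_id="s",
        tissue=tissue,
        marker_name=marker,
        peaks=[Peak(p, 10.0, 1.0) for p in sorted(positions)],
        hyperparameters=Hyperparameters(),
        total_reads=total_reads,
    )


class TestCompareMarker:
    def test_different_peak_counts_is_unstable(self):
        call = compare_marker(peak_set([20, 25]), peak_set([25], tissue="normal"))
        assert call.status == "unstable"

    def test_gap_of_one_is_stable(self):
        call = compare_marker(
            peak_set([25, 27]), peak_set([25, 26], tissue="normal")
        )
        assert call.status == "stable"
        assert call.max_position_gap == 1

    def test_gap_of_two_is_unstable(self):
        call = compare_marker(
            peak_set([23, 27]), peak_set([25, 27], tissue="normal")
        )
        assert call.status == "unstable"
        assert call.max_position_gap == 2

    def test_identical_peak_sets_are_stable(self):
        call = compare_marker(peak_set([22, 25]), peak_set([22, 25], tissue="normal"))
        assert call.status == "stable"
        assert call.max_position_gap == 0

    def test_minimum_unstable_shift_is_two(self):
        flips = [
            compare_marker(
                peak_set([25 + s]), peak_set([25], tissue="normal")
            ).status
            for s in range(4)
        ]
        assert flips == ["stable", "stable", "unstable", "unstable"]

    def test_status_symmetric_under_tumor_normal_swap(self):
        cases = [([25], [25]), ([20, 25], [25]), ([23, 27], [25, 27])]
        for tumor_pos, normal_pos in cases:
            a = compare_marker(peak_set(tumor_pos), peak_set(normal_pos, tissue="normal"))
            b = compare_marker(peak_set(normal_pos), peak_set(tumor_pos, tissue="normal"))
            assert a.status == b.status

    def test_low_depth_is_uninformative(self):
        call = compare_marker(
            peak_set([25], total_reads=5), peak_set([25], tissue="normal")
        )
        assert call.status == "uninformative"

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_marker(peak_set([25]), peak_set([25], marker="NR21"))


def marker_call(status, name="Bat25"):
    return MarkerCall(name, status, 1, 1, 0, "test")


class TestClassifyPatient:
    @pytest.mark.parametrize(
        "n_unstable, expected",
        [(0, "MSI-L"), (1, "MSI-L"), (2, "MSI-H"), (3, "MSI-H"), (6, "MSI-H")],
    )
    def test_msih_requires_at_least_two_unstable(self, n_unstable, expected):
        calls = [
            marker_call("unstable" if i < n_unstable else "stable", f"m{i}")
            for i in range(6)
        ]
        patient = classify_patient(calls, "p")
        assert patient.status == expected
        assert patient.n_unstable == n_unstable
        assert patient.n_evaluated == 6

    def test_uninformative_markers_excluded_from_evaluation(self):
        calls = [marker_call("unstable", f"u{i}") for i in range(3)]
        calls += [marker_call("uninformative", f"x{i}") for i in range(3)]
        patient = classify_patient(calls, "p")
        assert patient.status == "MSI-H"
        assert patient.n_evaluated == 3

    def test_all_uninformative_is_uncallable(self):
        with pytest.raises(UncallableError):
            classify_patient([marker_call("uninformative")], "p")

    def test_adding_an_unstable_marker_never_demotes_msih(self):
        base = [marker_call("unstable", "a"), marker_call("unstable", "b")]
        assert classify_patient(base, "p").status == "MSI-H"
        more = base + [marker_call("unstable", "c")]
        assert classify_patient(more, "p").status == "MSI-H"


class TestCallSamplePair:
    def _bams(self, tmp_path, panel, tumor_plan, normal_plan):
        tumor = write_fixture_bam(tumor_plan, panel, tmp_path / "t.bam", seed=1)
        normal = write_fixture_bam(normal_plan, panel, tmp_path / "n.bam", seed=2)
        return tumor, normal

    def test_two_shifted_markers_give_msih(self, tmp_path, panel):
        normal_plan = {m.name: {m.ref_repeat_length: 60} for m in panel}
        tumor_plan = {m.name: dict(v) for m, v in zip(panel, normal_plan.values())}
        for name in ("Bat25", "NR21"):
            marker = next(m for m in panel if m.name == name)
            tumor_plan[name][marker.ref_repeat_length - 6] = 40
        tumor, normal = self._bams(tmp_path, panel, tumor_plan, normal_plan)
        patient = call_sample_pair(tumor, normal, panel, sample_id="p1")
        assert patient.status == "MSI-H"
        assert patient.unstable_markers == ["Bat25", "NR21"]

    def test_identical_pair_is_msil(self, tmp_path, panel):
        plan = {m.name: {m.ref_repeat_length: 60} for m in panel}
        tumor, normal = self._bams(tmp_path, panel, plan, plan)
        patient = call_sample_pair(tumor, normal, panel, sample_id="p2")
        assert patient.status == "MSI-L"
        assert patient.n_unstable == 0

    def test_single_shifted_marker_is_msil(self, tmp_path, panel):
        normal_plan = {m.name: {m.ref_repeat_length: 60} for m in panel}
        tumor_plan = {m.name: dict(v) for m, v in zip(panel, normal_plan.values())}
        bat25 = next(m for m in panel if m.name == "Bat25")
        tumor_plan["Bat25"][bat25.ref_repeat_length - 6] = 40
        tumor, normal = self._bams(tmp_path, panel, tumor_plan, normal_plan)
        patient = call_sample_pair(tumor, normal, panel, sample_id="p3")
        assert patient.status == "MSI-L"
        assert patient.n_unstable == 1

    def test_determinism_byte_for_byte(self, tmp_path, panel):
        plan = {m.name: {m.ref_repeat_length: 60} for m in panel}
        tumor, normal = self._bams(tmp_path, panel, plan, plan)
        a = call_sample_pair(tumor, normal, panel, sample_id="p")
        b = call_sample_pair(tumor, normal, panel, sample_id="p")
        assert a.to_json() == b.to_json()
        assert [c.marker_name for c in a.marker_calls] == [m.name for m in panel]
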