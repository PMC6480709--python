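"""Dynalog parsing, writing, merging and leaf-error statistics."""

import math

import numpy as np
import pytest

from dynaverify import (
    CLINAC_DIALECT,
    NATIVE_DIALECT,
    DynalogField,
    DynalogRecord,
    leaf_errors,
    max_leaf_error,
    merge_banks,
    parse_bank_file,
    rms_error,
    write_bank_file,
)
from dynaverify.dynalog_io import DynalogBankFile
from dynaverify.exceptions import (
    ConsistencyError,
    DynalogParseError,
    DynalogStructureError,
    MergeError,
)


def _make_bank(bank_id="A", n_records=10, n_leaves=4, seed=0, tick=50):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        expected = np.round(rng.uniform(-5, 5, n_leaves), 3)
        actual = np.round(expected - rng.normal(0, 0.05, n_leaves), 3)
        records.append(DynalogRecord(
            time_ms=i * tick,
            beam_on=True,
            beam_hold=False,
            segment=i // 3,
            gantry_deg=round(180.0 + i, 1),
            jaws_cm=np.round(rng.uniform(3, 6, 4), 3),
            dose_fraction=round(i / (n_records - 1), 8),
            expected_cm=expected,
            actual_cm=actual,
        ))
    return DynalogBankFile(bank_id, "Clinac", {"field": "test"}, records)


@pytest.mark.parametrize("dialect", [CLINAC_DIALECT, NATIVE_DIALECT],
                         ids=["clinac", "native"])
def test_write_parse_round_trip(tmp_path, dialect):
    bank = _make_bank().quantized(dialect)
    path = tmp_path / "bank_a.dlg"
    write_bank_file(bank, path, dialect)
    assert parse_bank_file(path, dialect) == bank


def test_two_writes_byte_identical(tmp_path):
    bank = _make_bank()
    p1, p2 = tmp_path / "one.dlg", tmp_path / "two.dlg"
    write_bank_file(bank, p1, NATIVE_DIALECT)
    write_bank_file(bank, p2, NATIVE_DIALECT)
    assert p1.read_bytes() == p2.read_bytes()


def test_integer_positions_are_hundredths_of_mm(tmp_path):
    """Raw value 5000 in the fixed-point dialect is 5000 * 0.01 mm = 5 cm."""
    bank = _make_bank(n_records=2, n_leaves=1)
    bank.records[0].expected_cm = np.array([5.0])
    path = tmp_path / "a.dlg"
    write_bank_file(bank, path, CLINAC_DIALECT)
    line = path.read_text().splitlines()[6]  # first record line
    assert line.split(",")[10] == "5000"
    assert parse_bank_file(path, CLINAC_DIALECT).records[0].expected_cm[0] == 5.0


def test_missing_record_gap_preserved_with_warning(tmp_path, caplog):
    bank = _make_bank(n_records=6)
    del bank.records[3]  # 100 ms gap
    path = tmp_path / "a.dlg"
    write_bank_file(bank, path, NATIVE_DIALECT)
    with caplog.at_level("WARNING"):
        parsed = parse_bank_file(path, NATIVE_DIALECT)
    assert "spacing" in caplog.text
    assert [r.time_ms for r in parsed.records] == [0, 50, 100, 200, 250]


def test_malformed_line_names_line_number(tmp_path):
    bank = _make_bank(n_records=3, n_leaves=2)
    path = tmp_path / "a.dlg"
    write_bank_file(bank, path, CLINAC_DIALECT)
    lines = path.read_text().splitlines()
    lines[6] = lines[6] + ",999"  # extra column on record 2
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(DynalogParseError, match="line 7"):
        parse_bank_file(path, CLINAC_DIALECT)


def test_write_rejects_too_few_records(tmp_path):
    bank = _make_bank(n_records=10)
    bank.records = []
    with pytest.raises(DynalogStructureError):
        write_bank_file(bank, tmp_path / "a.dlg", NATIVE_DIALECT)


class TestMergeBanks:
    def test_shapes(self):
        field = merge_banks(_make_bank("A", 100, 60), _make_bank("B", 100, 60))
        assert len(field.records) == 100
        assert field.expected.shape == (100, 120)
        assert field.leaf_count_per_bank == 60

    def test_record_count_mismatch(self):
        b = _make_bank("B", 9)
        with pytest.raises(MergeError, match="mismatch"):
            merge_banks(_make_bank("A", 10), b)

    def test_disagreeing_gantry_names_record(self):
        a, b = _make_bank("A"), _make_bank("B")
        b.records[7].gantry_deg += 5.0
        with pytest.raises(ConsistencyError, match="record 7"):
            merge_banks(a, b)

    def test_wrong_bank_ids(self):
        with pytest.raises(MergeError):
            merge_banks(_make_bank("B"), _make_bank("B"))


class TestLeafErrorStats:
    def test_leaf_errors_direct(self):
        field = merge_banks(_make_bank("A"), _make_bank("B"))
        field.records[0].expected_cm[0] = 5.00
        field.records[0].actual_cm[0] = 4.98
        eps = leaf_errors(field)
        assert eps[0, 0] == pytest.approx(0.02)

    def test_errors_plus_actual_reconstruct_expected(self, gaussian_field):
        eps = leaf_errors(gaussian_field)
        recon = eps + gaussian_field.actual
        assert np.allclose(recon, gaussian_field.expected, rtol=0, atol=1e-15)

    def test_zero_error_field(self, zero_error_field):
        assert np.all(leaf_errors(zero_error_field) == 0)
        assert rms_error(zero_error_field) == 0.0
        assert max_leaf_error(zero_error_field) == 0.0

    def test_rms_hand_worked(self):
        """Two pairs with errors 0.3 and 0.4 mm: sqrt((0.09+0.16)/2)."""
        records = [
            DynalogRecord(i * 50, True, False, 0, 180.0, np.zeros(4), i,
                          expected_cm=np.array([e]), actual_cm=np.array([0.0]))
            for i, e in enumerate([0.03, 0.04])
        ]
        field = DynalogField(records, 1, 50)
        assert rms_error(field) == pytest.approx(math.sqrt((0.09 + 0.16) / 2),
                                                 abs=1e-12)

    def test_rms_matches_brute_force(self, gaussian_field):
        eps_mm = (gaussian_field.expected - gaussian_field.actual).ravel() * 10.0
        brute = math.sqrt(sum(e * e for e in eps_mm) / eps_mm.size)
        assert rms_error(gaussian_field) == pytest.approx(brute, rel=1e-12)

    def test_rms_le_mle_and_permutation_invariance(self, gaussian_field, rng):
        assert rms_error(gaussian_field) <= max_leaf_error(gaussian_field)
        perm = rng.permutation(len(gaussian_field.records))
        shuffled = DynalogField(
            [gaussian_field.records[i] for i in perm],
            gaussian_field.leaf_count_per_bank, gaussian_field.tick_ms,
        )
        assert rms_error(shuffled) == pytest.approx(rms_error(gaussian_field),
                                                    rel=1e-12)

    def test_max_leaf_error_of_mixed_signs(self):
        records = [
            DynalogRecord(0, True, False, 0, 0.0, np.zeros(4), 0.0,
                          expected_cm=np.array([0.01, -0.05, 0.03]),
                          actual_cm=np.zeros(3)),
            DynalogRecord(50, True, False, 0, 0.0, np.zeros(4), 1.0,
                          expected_cm=np.zeros(3), actual_cm=np.zeros(3)),
        ]
        field = DynalogField(records, 3, 50)
        assert max_leaf_error(field) == pytest.approx(0.5)  # mm

    def test_beam_on_only_filter(self, small_plan):
        from dynaverify import ErrorModel, simulate_field

        field = simulate_field(small_plan, ErrorModel("gaussian", sigma_mm=0.5, seed=2))
        for r in field.records[:20]:
            r.beam_on = False
            r.actual_cm = r.expected_cm + 1.0  # huge error on beam-off records
        assert rms_error(field, beam_on_only=True) < rms_error(field, beam_on_only=False)
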