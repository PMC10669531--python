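"""Survey data model: I/O round-trips, complete-case filtering, scoring, alpha."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famschool.survey_model import (
    ReliabilityError,
    SchemaError,
    cronbach_alpha,
    default_codebook,
    filter_complete_cases,
    load_participants,
    score_scales,
    write_participants,
)
from famschool.synthetic_data import default_config, generate_participants


@pytest.fixture(scope="module")
def small_cohort():
    return generate_participants(default_config(n=30, seed=3))


class TestIO:
    def test_header_only_file_yields_empty_collection(self, tmp_path, codebook):
        p = tmp_path / "empty.csv"
        p.write_text(",".join(codebook.columns) + "\n")
        assert load_participants(p, codebook) == []

    def test_round_trip_preserves_records_and_order(self, tmp_path, small_cohort, codebook):
        p = tmp_path / "cohort.csv"
        write_participants(small_cohort, p, codebook)
        assert load_participants(p, codebook) == small_cohort

    def test_blank_cell_flags_missing(self, tmp_path, small_cohort, codebook):
        p = tmp_path / "cohort.csv"
        write_participants(small_cohort, p, codebook)
        lines = p.read_text().splitlines()
        header = lines[0].split(",")
        row = lines[2].split(",")
        row[header.index("coh_03")] = ""
        lines[2] = ",".join(row)
        p.write_text("\n".join(lines) + "\n")
        records = load_participants(p, codebook)
        assert len(records) == len(small_cohort)
        assert sum(r.has_missing for r in records) == 1
        assert records[1].item_responses["cohesion"][2] is None

    def test_out_of_range_response_flagged_missing(self, tmp_path, small_cohort, codebook):
        p = tmp_path / "cohort.csv"
        write_participants(small_cohort, p, codebook)
        lines = p.read_text().splitlines()
        header = lines[0].split(",")
        row = lines[1].split(",")
        row[header.index("dsrsc_01")] = "7"  # DSRSC items are 0-2
        lines[1] = ",".join(row)
        p.write_text("\n".join(lines) + "\n")
        assert load_participants(p, codebook)[0].item_responses["dsrsc"][0] is None

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path, small_cohort, codebook):
        p = tmp_path / "cohort.csv"
        write_participants(small_cohort, p, codebook)
        lines = p.read_text().splitlines()
        cols = lines[0].split(",")
        drop = cols.index("pee_05")
        out = ["," .join(c for i, c in enumerate(line.split(",")) if i != drop) for line in lines]
        p.write_text("\n".join(out) + "\n")
        with pytest.raises(SchemaError, match="pee_05"):
            load_participants(p, codebook)

    def test_unparseable_cell_reports_coordinates(self, tmp_path, small_cohort, codebook):
        p = tmp_path / "cohort.csv"
        write_participants(small_cohort, p, codebook)
        lines = p.read_text().splitlines()
        header = lines[0].split(",")
        row = lines[3].split(",")
        row[header.index("aut_02")] = "often"
        lines[3] = ",".join(row)
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=r"row 2.*aut_02"):
            load_participants(p, codebook)


class TestCodebook:
    def test_yaml_round_trip(self, tmp_path, codebook):
        from famschool.survey_model import load_codebook, save_codebook

        p = tmp_path / "codebook.yaml"
        save_codebook(codebook, p)
        assert load_codebook(p) == codebook

    def test_duplicate_scale_names_rejected(self, codebook):
        from famschool.survey_model import Codebook

        with pytest.raises(ValueError, match="unique"):
            Codebook(scales=codebook.scales + codebook.scales[:1])


class TestCompleteCases:
    def test_filters_exactly_the_incomplete_records(self, small_cohort):
        broken = small_cohort[1]
        responses = dict(broken.item_responses)
        vals = list(responses["conflict"])
        vals[0] = None
        responses["conflict"] = tuple(vals)
        import dataclasses

        records = list(small_cohort)
        records[1] = dataclasses.replace(broken, item_responses=responses)
        kept = filter_complete_cases(records)
        assert len(kept) == len(records) - 1
        assert all(not r.has_missing for r in kept)

    def test_all_complete_is_identity(self, small_cohort):
        assert filter_complete_cases(small_cohort) == list(small_cohort)

    def test_recruitment_attrition_matches_binomial_expectation(self):
        # emulates a 2800-student recruitment with 12.7% row-level missingness
        cfg = default_config(n=2800, seed=11, missingness_rate=0.127)
        kept = filter_complete_cases(generate_participants(cfg))
        expected = 2800 * (1 - 0.127)  # ~2444
        tol = 3 * np.sqrt(2800 * 0.127 * 0.873)
        assert abs(len(kept) - expected) < tol


class TestScoring:
    def test_known_totals(self, small_cohort, codebook):
        import dataclasses

        rec = small_cohort[0]
        responses = dict(rec.item_responses)
        responses["cohesion"] = (5,) * 16
        responses["dsrsc"] = (1,) * 18
        responses["conflict"] = (1, 0, 1, 0, 0, 0, 0, 0, 0)
        rec = dataclasses.replace(rec, item_responses=responses)
        scored = score_scales(rec, codebook)
        assert scored.scale_totals["cohesion"] == 80
        assert scored.depression_score == 18
        assert scored.scale_totals["conflict"] == 2

    def test_missing_item_is_an_error(self, small_cohort, codebook):
        import dataclasses

        rec = small_cohort[0]
        responses = dict(rec.item_responses)
        responses["peer_support"] = (None,) + rec.item_responses["peer_support"][1:]
        rec = dataclasses.replace(rec, item_responses=responses)
        with pytest.raises(ValueError, match="missing"):
            score_scales(rec, codebook)

    def test_totals_bounded_and_permutation_invariant(self, small_cohort, codebook):
        import dataclasses
        import random

        rng = random.Random(0)
        for rec in small_cohort:
            scored = score_scales(rec, codebook)
            shuffled = {
                name: tuple(rng.sample(vals, len(vals)))
                for name, vals in rec.item_responses.items()
            }
            rescored = score_scales(dataclasses.replace(rec, item_responses=shuffled), codebook)
            assert scored.scale_totals == rescored.scale_totals
            for scale in codebook.scales:
                assert (
                    scale.min_total
                    <= scored.scale_totals[scale.name]
                    <= scale.max_total
                )


class TestCronbachAlpha:
    def test_two_identical_items_give_alpha_one(self):
        x = np.array([[1, 1], [2, 2], [3, 3], [5, 5]])
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        x = np.array([[1, 2, 1], [2, 1, 2], [3, 3, 2], [4, 4, 4]])
        # item variances 1.6667, 1.6667, 1.5833; total variance 12.9167
        assert cronbach_alpha(x) == pytest.approx(0.929, abs=5e-4)

    def test_constant_respondents_raise(self):
        with pytest.raises(ReliabilityError):
            cronbach_alpha(np.ones((5, 3)))

    @pytest.mark.parametrize("k,rho", [(5, 0.3), (10, 0.15)])
    def test_compound_symmetry_convergence(self, k, rho):
        # alpha of a compound-symmetric Gaussian matrix -> k*rho/(1+(k-1)*rho)
        rng = np.random.default_rng(42)
        n = 20_000
        z = rng.standard_normal((n, 1))
        x = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal((n, k))
        expected = k * rho / (1 + (k - 1) * rho)
        assert cronbach_alpha(x) == pytest.approx(expected, abs=0.02)

    @given(st.integers(2, 6), st.integers(5, 30), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_alpha_at_most_one_for_positive_covariance(self, k, n, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, 1))
        x = z + 0.7 * rng.standard_normal((n, k))
        try:
            a = cronbach_alpha(x)
        except ReliabilityError:
            return
        assert a <= 1.0 + 1e-12
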