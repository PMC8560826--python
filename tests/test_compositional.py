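"""Compositional transforms: closure, alr/clr, Procrustes, reference choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import procrustes as scipy_procrustes

from alrpls import (
    AbundanceTable,
    alr_inverse,
    alr_transform,
    clr_coordinates,
    evaluate_reference_candidates,
    procrustes_correlation,
    select_reference,
    to_relative,
)


def _table(values, kind="counts"):
    values = np.asarray(values, dtype=float)
    n, j = values.shape
    return AbundanceTable(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{k}" for k in range(j)],
        kind=kind,
    )


class TestToRelative:
    def test_direct_closure(self):
        rel = to_relative(_table([[2, 3, 5]]))
        assert np.allclose(rel.values, [[0.2, 0.3, 0.5]])
        assert rel.kind == "relative"

    def test_idempotent_on_relative_rows(self, tiny_relative):
        again = to_relative(tiny_relative)
        assert np.allclose(again.values, tiny_relative.values)

    def test_rows_sum_to_one(self, rng):
        rel = to_relative(_table(rng.uniform(0.1, 50, size=(20, 30))))
        assert np.allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_sum_row_rejected(self):
        with pytest.raises(ValueError, match="row sum"):
            to_relative(_table([[0, 0, 0], [1, 2, 3]]))


class TestAlr:
    def test_formula(self):
        alr = alr_transform(_table([[0.2, 0.3, 0.5]], kind="relative"), "f2")
        assert np.allclose(alr.values, [[np.log(0.4), np.log(0.6)]], atol=1e-12)
        assert alr.reference_id == "f2"
        assert alr.feature_ids == ["f0", "f1"]

    def test_equal_composition_gives_zeros(self):
        alr = alr_transform(_table([[0.25] * 4], kind="relative"), "f0")
        assert np.allclose(alr.values, 0.0)

    def test_scale_invariance(self, tiny_relative):
        scaled = AbundanceTable(
            values=tiny_relative.values * np.array([[2.0], [3.0], [0.5], [10.0]]),
            sample_ids=tiny_relative.sample_ids,
            feature_ids=tiny_relative.feature_ids,
            kind="counts",
        )
        a = alr_transform(tiny_relative, "f1")
        b = alr_transform(to_relative(scaled), "f1")
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_unknown_reference(self, tiny_relative):
        with pytest.raises(KeyError):
            alr_transform(tiny_relative, "nope")

    def test_nonpositive_rejected(self):
        t = _table([[0.5, 0.5, 0.0]], kind="counts")
        with pytest.raises(ValueError, match="positive"):
            alr_transform(t, "f0")

    def test_inverse_roundtrip(self, tiny_relative):
        alr = alr_transform(tiny_relative, "f3")
        back = alr_inverse(alr)
        frame = back.to_frame()[tiny_relative.feature_ids]
        assert np.allclose(frame.to_numpy(), tiny_relative.values, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_subcompositional_coherence(self, seed):
        """Dropping an uninvolved part and re-closing leaves a ratio unchanged."""
        rng = np.random.default_rng(seed)
        j = int(rng.integers(4, 9))
        rel = to_relative(_table(rng.uniform(0.05, 20, size=(5, j))))
        full = alr_transform(rel, f"f{j - 1}")
        drop = 1  # uninvolved in the f0 / f(j-1) ratio
        keep = [k for k in range(j) if k != drop]
        sub = to_relative(
            AbundanceTable(
                values=rel.values[:, keep],
                sample_ids=rel.sample_ids,
                feature_ids=[f"f{k}" for k in keep],
                kind="counts",
            )
        )
        sub_alr = alr_transform(sub, f"f{j - 1}")
        assert np.allclose(
            full.to_frame()["f0"], sub_alr.to_frame()["f0"], atol=1e-12
        )


class TestClr:
    def test_equal_composition_row_is_zero(self):
        clr = clr_coordinates(_table([[0.25] * 4], kind="relative"))
        assert np.allclose(clr, 0.0)

    def test_rows_center_to_zero(self, tiny_relative):
        clr = clr_coordinates(tiny_relative)
        assert np.allclose(clr.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("j", [3, 5, 8])
    def test_distances_match_pairwise_logratio_bruteforce(self, rng, j):
        """clr Euclidean distance = Aitchison distance from all J(J-1)/2 ratios."""
        rel = to_relative(_table(rng.uniform(0.1, 10, size=(6, j))))
        clr = clr_coordinates(rel)
        log_x = np.log(rel.values)
        for a in range(6):
            for b in range(a + 1, 6):
                acc = 0.0
                for p in range(j):
                    for q in range(p + 1, j):
                        d = (log_x[a, p] - log_x[a, q]) - (log_x[b, p] - log_x[b, q])
                        acc += d * d
                brute = np.sqrt(acc / j)
                assert np.isclose(
                    np.linalg.norm(clr[a] - clr[b]), brute, atol=1e-10
                )


class TestProcrustes:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=(12, 4))
        assert procrustes_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_similarity_transform_invariance(self, rng):
        x = rng.normal(size=(15, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        y = 3.2 * x @ rot + np.array([1.0, -2.0, 0.5])
        assert procrustes_correlation(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle_on_random_pairs(self, rng):
        """corr = sqrt(1 - m2) with m2 the scipy normalized Procrustes residual."""
        for _ in range(100):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            _, _, m2 = scipy_procrustes(a, b)
            assert procrustes_correlation(a, b) == pytest.approx(
                np.sqrt(1 - m2), abs=1e-9
            )

    def test_symmetry(self, rng):
        a = rng.normal(size=(9, 4))
        b = rng.normal(size=(9, 4))
        assert procrustes_correlation(a, b) == pytest.approx(
            procrustes_correlation(b, a), abs=1e-10
        )

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="row counts"):
            procrustes_correlation(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))

    def test_degenerate_configuration_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_correlation(np.ones((5, 2)), rng.normal(size=(5, 2)))

    def test_column_padding(self, rng):
        """1-D configurations are padded; identical ones still correlate at 1."""
        x = rng.normal(size=(8, 1))
        assert procrustes_correlation(x, 2.0 * x) == pytest.approx(1.0, abs=1e-9)


class TestReferenceEvaluation:
    def test_cv_matches_direct_recomputation(self, tiny_relative, rng):
        trait = rng.normal(size=4)
        report = evaluate_reference_candidates(tiny_relative, trait)
        log_rel = np.log(tiny_relative.values)
        for k, fid in enumerate(tiny_relative.feature_ids):
            lr = log_rel[:, k]
            expected = 100 * lr.std(ddof=1) / abs(lr.mean())
            assert report.loc[fid, "logrel_cv_pct"] == pytest.approx(expected, rel=1e-12)
            assert report.loc[fid, "logrel_variance"] == pytest.approx(
                lr.var(ddof=1), rel=1e-12
            )

    def test_constant_trait_flagged_not_fatal(self, tiny_relative):
        report = evaluate_reference_candidates(tiny_relative, np.ones(4))
        assert report["trait_constant"].all()
        assert report["trait_corr"].isna().all()

    def test_near_constant_feature_low_variance(self, rng):
        vals = rng.uniform(1, 5, size=(30, 6))
        vals[:, 2] = 100.0  # constant, dominant feature
        rel = to_relative(_table(vals))
        report = evaluate_reference_candidates(rel, rng.normal(size=30))
        assert report["logrel_variance"].idxmin() == "f2"


class TestSelectReference:
    def _report(self, rel, trait):
        return evaluate_reference_candidates(rel, trait)

    def test_single_passing_candidate_wins(self, rng):
        vals = rng.uniform(1, 5, size=(40, 8))
        vals[:, 0] = 50.0
        rel = to_relative(_table(vals))
        report = self._report(rel, rng.normal(size=40))
        keep = report.loc[["f0"]].copy()
        sel = select_reference(keep, min_procrustes=0.0)
        assert sel.reference_id == "f0"

    def test_variance_rule_breaks_ties(self, rng):
        vals = rng.uniform(1, 5, size=(50, 10))
        vals[:, 3] = 80.0 * rng.uniform(0.999, 1.001, size=50)
        vals[:, 7] = 80.0 * rng.uniform(0.9, 1.1, size=50)
        rel = to_relative(_table(vals))
        report = self._report(rel, rng.normal(size=50))
        sel = select_reference(report, min_procrustes=0.0)
        assert sel.reference_id == "f3"

    def test_no_survivor_raises_with_advice(self, tiny_relative, rng):
        report = self._report(tiny_relative, rng.normal(size=4))
        with pytest.raises(ValueError, match="relax"):
            select_reference(report, min_procrustes=1.01)

    def test_empty_report_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            select_reference(pd.DataFrame())

    def test_audit_json_lists_winner(self, rng):
        vals = rng.uniform(1, 5, size=(40, 8))
        vals[:, 0] = 50.0
        rel = to_relative(_table(vals))
        report = self._report(rel, rng.normal(size=40))
        sel = select_reference(report, min_procrustes=0.0)
        import json

        audit = json.loads(sel.audit_json())
        assert audit["reference_id"] == sel.reference_id
        assert audit["n_candidates"] == 8
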