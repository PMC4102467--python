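"""MCC, its significance transform, eligibility rules, and the variant-subset
search against a brute-force oracle."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from varpharm.drug_response import DrugActivityMatrix
from varpharm.io_formats import ChangeType
from varpharm.variant_drug_association import (
    RESISTANCE,
    SENSITIVITY,
    AssociationResult,
    ContingencyTable,
    ScreenConfig,
    association_screen,
    best_variant_combination,
    binarize_drug_response,
    eligible_variants,
    matthews_correlation,
    mcc_significance,
    provenance_partition,
)

from conftest import make_record


def mcc_pearson_oracle(table):
    """MCC as the Pearson correlation of the expanded 0/1 vectors."""
    carrier = [1] * (table.tp + table.fp) + [0] * (table.fn + table.tn)
    responder = [1] * table.tp + [0] * table.fp + [1] * table.fn + [0] * table.tn
    if not carrier:
        return 0.0
    x, y = np.asarray(carrier, float), np.asarray(responder, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


class TestMatthewsCorrelation:
    @pytest.mark.parametrize(
        "tp, fp, fn, tn, expected",
        [
            (9, 1, 0, 49, 0.94),  # vemurafenib-style sensitivity pairing
            (3, 0, 1, 45, 0.86),
            (5, 0, 0, 5, 1.0),
        ],
    )
    def test_worked_examples(self, tp, fp, fn, tn, expected):
        assert round(matthews_correlation(ContingencyTable(tp, fp, fn, tn)), 2) == expected

    def test_degenerate_marginals_give_zero(self):
        assert matthews_correlation(ContingencyTable(0, 0, 3, 7)) == 0.0
        assert matthews_correlation(ContingencyTable(3, 7, 0, 0)) == 0.0
        assert matthews_correlation(ContingencyTable(0, 3, 0, 7)) == 0.0

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=300, deadline=None)
    def test_equals_binary_pearson(self, tp, fp, fn, tn):
        table = ContingencyTable(tp, fp, fn, tn)
        assert matthews_correlation(table) == pytest.approx(
            mcc_pearson_oracle(table), abs=1e-12
        )
        assert -1.0 <= matthews_correlation(table) <= 1.0

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_symmetries(self, tp, fp, fn, tn):
        m = matthews_correlation(ContingencyTable(tp, fp, fn, tn))
        # swapping carriers' and non-carriers' roles jointly preserves MCC
        assert matthews_correlation(ContingencyTable(tn, fn, fp, tp)) == pytest.approx(m)
        # inverting the response labels negates it
        assert matthews_correlation(ContingencyTable(fp, tp, tn, fn)) == pytest.approx(-m)


class TestMccSignificance:
    def test_gate_calibration(self):
        assert mcc_significance(0.596, 35) <= 0.0002

    def test_null_mcc_gives_p_one(self):
        assert mcc_significance(0.0, 10) == pytest.approx(1.0)
        assert mcc_significance(0.0, 60) == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self):
        mcc, n = 0.5, 20
        df = n - 2
        t = mcc * math.sqrt(df) / math.sqrt(1 - mcc**2)

        def t_pdf(x):
            return (
                math.gamma((df + 1) / 2)
                / (math.sqrt(df * math.pi) * math.gamma(df / 2))
                * (1 + x * x / df) ** (-(df + 1) / 2)
            )

        tail, _ = integrate.quad(t_pdf, t, math.inf)
        assert mcc_significance(mcc, n) == pytest.approx(2 * tail, rel=1e-8)

    def test_perfect_mcc_smallest_positive(self):
        p = mcc_significance(1.0, 10)
        assert 0 < p < 1e-300

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            mcc_significance(0.5, 2)


class TestBinarize:
    def test_directions(self):
        z = pd.Series({"A:1": 0.6, "A:2": -0.6, "A:3": 0.0})
        resp, ev = binarize_drug_response(z, SENSITIVITY)
        assert resp == {"A:1"} and ev == {"A:1", "A:2", "A:3"}
        resp, _ = binarize_drug_response(z, RESISTANCE)
        assert resp == {"A:2"}

    def test_boundary_is_a_response(self):
        z = pd.Series({"A:1": 0.5, "A:2": -0.5})
        assert binarize_drug_response(z, SENSITIVITY)[0] == {"A:1"}
        assert binarize_drug_response(z, RESISTANCE)[0] == {"A:2"}

    def test_missing_excluded_from_evaluable(self):
        z = pd.Series({"A:1": float("nan"), "A:2": 1.0})
        resp, ev = binarize_drug_response(z, SENSITIVITY)
        assert ev == {"A:2"} and resp == {"A:2"}

    def test_all_missing(self):
        z = pd.Series({"A:1": float("nan")})
        resp, ev = binarize_drug_response(z, SENSITIVITY)
        assert ev == frozenset() and resp == frozenset()


class TestEligibility:
    def test_carrier_cap_excludes_thirteen_lines(self):
        common = make_record("G", "chr1:100_A_G",
                             percents={f"A:{i}": 50.0 for i in range(13)})
        rare = make_record("G", "chr1:200_A_G", percents={"A:0": 50.0})
        assert eligible_variants([common, rare]) == [rare]

    def test_silent_and_flagged_excluded(self):
        silent = make_record("G", "chr1:100_A_G", ChangeType.SILENT,
                             percents={"A:0": 50.0})
        segdup = make_record("G", "chr1:200_A_G", percents={"A:0": 50.0}, in_segdup=True)
        multi = make_record("G", "chr1:300_A_G", percents={"A:0": 50.0}, multimap=True)
        ok = make_record("G", "chr1:400_A_G", percents={"A:0": 50.0})
        assert eligible_variants([silent, segdup, multi, ok]) == [ok]

    def test_normal_presence_is_not_a_criterion(self):
        present = make_record("G", "chr1:100_A_G", percents={"A:0": 50.0},
                              freq_esp5400=0.05)
        assert eligible_variants([present]) == [present]

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError):
            eligible_variants([make_record("A"), make_record("B", "chr1:2_A_G")])


def brute_force_best(variants, responders, evaluable, config=ScreenConfig()):
    """Independent subset-search oracle: sets and itertools, no bitmasks."""
    best = None
    ordered = sorted(variants, key=lambda r: r.variant_id)
    for size in range(1, min(config.max_subset_size, len(ordered)) + 1):
        for combo in combinations(ordered, size):
            union = set()
            for rec in combo:
                union |= {l for l in evaluable if rec.percent_in(l) > 0}
            tp = len(union & responders)
            fp = len(union - responders)
            fn = len(responders - union)
            tn = len(evaluable) - tp - fp - fn
            table = ContingencyTable(tp, fp, fn, tn)
            m = matthews_correlation(table)
            key = (m, -size, table.precision,
                   tuple(sorted(r.variant_id for r in combo)))
            if best is None or key[:3] > best[0][:3] or (
                key[:3] == best[0][:3] and key[3] < best[0][3]
            ):
                best = (key, combo, table)
    if best is None:
        return None
    key, combo, table = best
    return tuple(sorted(r.variant_id for r in combo)), key, table


def random_gene(rng, n_variants, n_lines=20):
    lines = [f"T:{i:02d}" for i in range(n_lines)]
    variants = []
    for v in range(n_variants):
        carriers = rng.choice(n_lines, size=rng.integers(1, 7), replace=False)
        variants.append(
            make_record(
                "G", f"chr1:{1000 + v}_A_G",
                percents={lines[i]: 50.0 for i in carriers},
            )
        )
    responders = frozenset(
        lines[i] for i in rng.choice(n_lines, size=rng.integers(2, 9), replace=False)
    )
    return variants, responders, frozenset(lines)


class TestBestVariantCombination:
    LOOSE = ScreenConfig(mcc_min=-1.0, precision_min=0.0,
                         gene_precision_min=0.0, min_consistent_cells=0)

    def test_single_variant_vemurafenib_shape(self):
        # 10 carriers (9 responders + 1 non), 49 non-carrier non-responders
        lines = [f"L:{i:02d}" for i in range(59)]
        carriers = lines[:10]
        responders = frozenset(carriers[:9])
        rec = make_record("BRAF", "chr7:140453136_A_T",
                          percents={l: 100.0 for l in carriers})
        hit = best_variant_combination([rec], responders, frozenset(lines))
        assert hit is not None
        assert (hit.table.tp, hit.table.fp, hit.table.fn, hit.table.tn) == (9, 1, 0, 49)
        assert round(hit.mcc, 2) == 0.94

    def test_optimal_pair_beats_singles(self):
        lines = [f"L:{i}" for i in range(12)]
        v1 = make_record("G", "chr1:100_A_G", percents={lines[0]: 50, lines[1]: 50})
        v2 = make_record("G", "chr1:200_A_G", percents={lines[2]: 50, lines[3]: 50})
        v3 = make_record("G", "chr1:300_A_G", percents={lines[4]: 50, lines[10]: 50})
        responders = frozenset(lines[:4])
        hit = best_variant_combination([v1, v2, v3], responders, frozenset(lines),
                                       self.LOOSE)
        assert hit.variant_subset == ("chr1:100_A_G", "chr1:200_A_G")
        assert hit.mcc == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            variants, responders, evaluable = random_gene(rng, int(rng.integers(1, 8)))
            hit = best_variant_combination(variants, responders, evaluable, self.LOOSE)
            subset, key, _ = brute_force_best(variants, responders, evaluable, self.LOOSE)
            assert hit is not None
            assert tuple(sorted(hit.variant_subset)) == subset
            assert hit.mcc == pytest.approx(key[0], abs=1e-12)

    def test_gates_suppress_weak_hits(self):
        lines = [f"L:{i}" for i in range(20)]
        rec = make_record("G", "chr1:100_A_G", percents={lines[0]: 50})
        hit = best_variant_combination([rec], frozenset(lines[5:10]), frozenset(lines))
        assert hit is None

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(3)
        greedy_cfg = ScreenConfig(mcc_min=-1.0, precision_min=0.0,
                                  gene_precision_min=0.0, min_consistent_cells=0,
                                  exhaustive_max_variants=0)
        for _ in range(30):
            variants, responders, evaluable = random_gene(rng, int(rng.integers(2, 10)))
            exhaustive = best_variant_combination(variants, responders, evaluable,
                                                  self.LOOSE)
            greedy = best_variant_combination(variants, responders, evaluable,
                                              greedy_cfg)
            if greedy is not None:
                assert greedy.greedy
                assert greedy.mcc <= exhaustive.mcc + 1e-12


class TestAssociationScreen:
    def test_planted_pairs_recovered_exactly(self):
        from varpharm.synthetic_data import PlantedPair, SimulationConfig, simulate_panel

        config = SimulationConfig(
            n_genes=20,
            n_drugs=10,
            seed=11,
            planted_pairs=(
                PlantedPair("GENE03", "700002", SENSITIVITY, 4.0),
                PlantedPair("GENE07", "700005", RESISTANCE, 4.0),
            ),
        )
        catalog, matrix, _ = simulate_panel(config)
        sens, res = association_screen(catalog, matrix)
        assert ("GENE03", "700002") in set(zip(sens.gene, sens.nsc))
        assert ("GENE07", "700005") in set(zip(res.gene, res.nsc))

    def test_empty_drug_matrix(self):
        drugs = pd.DataFrame(columns=["nsc", "name", "moa", "status"])
        matrix = DrugActivityMatrix(drugs=drugs, z=pd.DataFrame(columns=["A:1"]))
        sens, res = association_screen([make_record(percents={"A:1": 50.0})], matrix)
        assert sens.empty and res.empty

    def test_disjoint_panels_error(self):
        drugs = pd.DataFrame(
            {"nsc": ["1"], "name": ["d"], "moa": ["YK"], "status": ["other"]},
            index=["1"],
        )
        matrix = DrugActivityMatrix(
            drugs=drugs, z=pd.DataFrame([[0.1, -0.1]], index=["1"], columns=["X:1", "X:2"])
        )
        with pytest.raises(ValueError, match="share no cell lines"):
            association_screen([make_record(percents={"Y:1": 50.0})], matrix)


class TestProvenancePartition:
    def result(self, p, vids):
        return AssociationResult(
            gene="G", nsc="1", direction=SENSITIVITY, variant_subset=tuple(vids),
            table=ContingencyTable(3, 0, 0, 10), mcc=1.0, p=p,
            gene_overall_precision=1.0,
        )

    def records_by_id(self):
        absent = make_record("G", "chr1:100_A_G")
        present = make_record("G", "chr1:200_A_G", freq_esp5400=0.05)
        return {r.variant_id: r for r in (absent, present)}

    def test_all_absent(self):
        table = provenance_partition(
            [self.result(1e-9, ["chr1:100_A_G"])], self.records_by_id()
        )
        assert len(table) == 4
        assert (table.frac_absent == 1.0).all() and (table.frac_present == 0.0).all()

    def test_mixed_hand_tally(self):
        results = [
            self.result(1e-5, ["chr1:100_A_G", "chr1:200_A_G"]),
            self.result(0.01, ["chr1:200_A_G"]),
        ]
        table = provenance_partition(results, self.records_by_id()).set_index("p_threshold")
        row = table.loc[0.05]
        assert (row.n_absent, row.n_present) == (1, 2)
        row = table.loc[2e-4]
        assert (row.n_absent, row.n_present) == (1, 1)
        assert row.frac_absent + row.frac_present == pytest.approx(1.0)

    def test_threshold_count_drives_row_count(self):
        table = provenance_partition([], self.records_by_id(), p_thresholds=[0.05, 0.01])
        assert len(table) == 2
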