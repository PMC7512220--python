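"""Rollup / normalization / averaging against independent brute-force oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

import swathms as sm
from swathms.errors import DegenerateRunError, ReferentialIntegrityError


def _runs(n, reps=1):
    rows = []
    for s in range(n):
        for k in range(reps):
            rows.append((f"S{s}_r{k+1}", f"S{s}", k + 1))
    return pd.DataFrame(rows, columns=["run_id", "sample_id", "replicate_index"])


def _random_fragment_table(rng, n_prot=5, max_pep=15, max_frag=9, n_runs=4, missing=0.3):
    runs = _runs(n_runs)
    rows = []
    for p in range(n_prot):
        for q in range(rng.integers(1, max_pep + 1)):
            for f in range(rng.integers(1, max_frag + 1)):
                for r in runs["run_id"]:
                    if rng.random() < missing:
                        continue
                    rows.append(
                        (f"P{p}", f"P{p}_pep{q:02d}", f"P{p}_pep{q:02d}_f{f}", r,
                         float(rng.lognormal(3, 1)))
                    )
    frags = pd.DataFrame(
        rows, columns=["protein_id", "peptide_id", "fragment_id", "run_id", "intensity"]
    )
    return frags, runs


def _brute_force_rollup(frags, runs, top_peptides, top_fragments):
    """Independent oracle: explicit dict-based enumeration and ranking."""
    out = {}
    run_ids = list(runs["run_id"])
    for prot, pdf in frags.groupby("protein_id"):
        # fragment strengths across runs
        frag_strength = {}
        for (pep, frag), fdf in pdf.groupby(["peptide_id", "fragment_id"]):
            frag_strength[(pep, frag)] = fdf["intensity"].sum()
        pep_strength = {}
        for (pep, frag), s in frag_strength.items():
            pep_strength[pep] = pep_strength.get(pep, 0.0) + s
        top_peps = sorted(pep_strength, key=lambda p: (-pep_strength[p], p))[:top_peptides]
        selected = set()
        for pep in top_peps:
            frs = [(f, s) for (pp, f), s in frag_strength.items() if pp == pep]
            frs.sort(key=lambda t: (-t[1], t[0]))
            for f, _ in frs[:top_fragments]:
                selected.add((pep, f))
        vals = {r: 0.0 for r in run_ids}
        for _, row in pdf.iterrows():
            if (row["peptide_id"], row["fragment_id"]) in selected:
                vals[row["run_id"]] += row["intensity"]
        out[prot] = vals
    proteins = sorted(out)
    return pd.DataFrame(
        [[out[p][r] for r in run_ids] for p in proteins], index=proteins, columns=run_ids
    )


def test_rollup_sums_all_when_fewer_than_top_n():
    runs = _runs(1)
    frags = pd.DataFrame(
        {
            "protein_id": ["A"] * 3,
            "peptide_id": ["A_p1"] * 3,
            "fragment_id": ["A_p1_f1", "A_p1_f2", "A_p1_f3"],
            "run_id": ["S0_r1"] * 3,
            "intensity": [10.0, 20.0, 30.0],
        }
    )
    mat = sm.rollup_protein_intensity(frags, runs)
    assert mat.stage == "raw"
    assert mat.data.loc["A", "S0_r1"] == 60.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rollup_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    frags, runs = _random_fragment_table(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mat = sm.rollup_protein_intensity(frags, runs)
    oracle = _brute_force_rollup(frags, runs, 10, 6)
    np.testing.assert_allclose(mat.data.to_numpy(), oracle.to_numpy(), rtol=1e-9)
    assert list(mat.data.index) == list(oracle.index)


def test_rollup_with_selection_pressure_matches_oracle():
    # more peptides/fragments than the top-N cut, so ranking actually selects
    rng = np.random.default_rng(42)
    frags, runs = _random_fragment_table(rng, n_prot=3, max_pep=15, max_frag=9, missing=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = sm.rollup_protein_intensity(frags, runs, top_peptides=4, top_fragments=3)
    oracle = _brute_force_rollup(frags, runs, 4, 3)
    np.testing.assert_allclose(top.data.to_numpy(), oracle.to_numpy(), rtol=1e-9)


def test_rollup_row_order_invariance():
    rng = np.random.default_rng(3)
    frags, runs = _random_fragment_table(rng)
    shuffled = frags.sample(frac=1.0, random_state=9).reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = sm.rollup_protein_intensity(frags, runs)
        b = sm.rollup_protein_intensity(shuffled, runs)
    pd.testing.assert_frame_equal(a.data, b.data)


def test_rollup_monotone_in_selected_fragment():
    runs = _runs(1)
    frags = pd.DataFrame(
        {
            "protein_id": ["A", "A"],
            "peptide_id": ["A_p1", "A_p1"],
            "fragment_id": ["A_p1_f1", "A_p1_f2"],
            "run_id": ["S0_r1", "S0_r1"],
            "intensity": [10.0, 5.0],
        }
    )
    base = sm.rollup_protein_intensity(frags, runs).data.iloc[0, 0]
    frags.loc[0, "intensity"] += 1.0
    bumped = sm.rollup_protein_intensity(frags, runs).data.iloc[0, 0]
    assert bumped > base


def test_rollup_unknown_run_raises():
    runs = _runs(1)
    frags = pd.DataFrame(
        {
            "protein_id": ["A"],
            "peptide_id": ["A_p1"],
            "fragment_id": ["A_p1_f1"],
            "run_id": ["GHOST"],
            "intensity": [1.0],
        }
    )
    with pytest.raises(ReferentialIntegrityError, match="GHOST"):
        sm.rollup_protein_intensity(frags, runs)


def test_normalize_equalizes_column_sums_and_preserves_ratios():
    rng = np.random.default_rng(8)
    data = pd.DataFrame(
        rng.lognormal(2, 1, size=(20, 6)),
        index=[f"P{i}" for i in range(20)],
        columns=[f"r{i}" for i in range(6)],
    )
    raw = sm.ProteinMatrix(data, "raw")
    norm = sm.total_sum_normalize(raw)
    sums = norm.data.sum(axis=0)
    np.testing.assert_allclose(sums, sums.iloc[0], rtol=1e-9)
    np.testing.assert_allclose(sums.iloc[0], data.sum(axis=0).mean(), rtol=1e-12)
    # within-column ratios preserved exactly
    for c in data.columns:
        np.testing.assert_allclose(
            norm.data[c] / norm.data[c].sum(), data[c] / data[c].sum(), rtol=1e-12
        )


def test_normalize_identity_when_totals_equal():
    data = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 2.0]}, index=["P1", "P2"])
    norm = sm.total_sum_normalize(sm.ProteinMatrix(data, "raw"))
    pd.testing.assert_frame_equal(norm.data, data)


def test_normalize_forced_totals_example():
    data = pd.DataFrame({"a": [100.0], "b": [300.0]}, index=["P1"])
    norm = sm.total_sum_normalize(sm.ProteinMatrix(data, "raw"))
    assert norm.data["a"].sum() == pytest.approx(200.0)
    assert norm.data["b"].sum() == pytest.approx(200.0)


def test_normalize_zero_total_column_names_run():
    data = pd.DataFrame({"good": [1.0], "dead": [0.0]}, index=["P1"])
    with pytest.raises(DegenerateRunError, match="dead"):
        sm.total_sum_normalize(sm.ProteinMatrix(data, "raw"))


def test_average_replicates_matches_per_sample_mean():
    rng = np.random.default_rng(4)
    runs = _runs(3, reps=3)
    data = pd.DataFrame(
        rng.lognormal(2, 1, size=(10, 9)),
        index=[f"P{i}" for i in range(10)],
        columns=list(runs["run_id"]),
    )
    norm = sm.ProteinMatrix(data, "normalized")
    avg = sm.average_replicates(norm, runs)
    assert avg.stage == "averaged"
    assert list(avg.data.columns) == ["S0", "S1", "S2"]
    for s in avg.data.columns:
        cols = [r for r, smp in zip(runs["run_id"], runs["sample_id"]) if smp == s]
        np.testing.assert_allclose(avg.data[s], data[cols].mean(axis=1), rtol=1e-12)


def test_average_replicates_arithmetic_mean_example():
    runs = _runs(1, reps=3)
    data = pd.DataFrame([[2.0, 4.0, 9.0]], index=["P1"], columns=list(runs["run_id"]))
    avg = sm.average_replicates(sm.ProteinMatrix(data, "normalized"), runs)
    assert avg.data.loc["P1", "S0"] == pytest.approx(5.0)


def test_stage_transitions_are_enforced():
    data = pd.DataFrame({"a": [1.0]}, index=["P1"])
    avg = sm.ProteinMatrix(data, "averaged")
    with pytest.raises(ValueError, match="stage"):
        sm.total_sum_normalize(avg)
    with pytest.raises(ValueError, match="stage"):
        sm.average_replicates(sm.ProteinMatrix(data, "raw"), _runs(1))
    with pytest.raises(ValueError, match="negative"):
        sm.ProteinMatrix(pd.DataFrame({"a": [-1.0]}), "raw")


def test_run_depth_spread_removed_by_normalization():
    """Pipelines with and without per-run depth spread agree after normalization.

    The depth factor multiplies whole runs, so total-sum normalization removes
    it exactly up to the (documented) global target constant.
    """
    base = dict(n_proteins=30, n_de_proteins=5, missing_rate=0.0, seed=17,
                peptides_per_protein=(3, 6), fragments_per_peptide=(4, 6))
    flat = sm.generate_cohort(sm.CohortConfig(run_depth_factor_sd=0.0, **base))
    deep = sm.generate_cohort(sm.CohortConfig(run_depth_factor_sd=0.4, **base))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n_flat = sm.total_sum_normalize(sm.rollup_protein_intensity(flat.fragments, flat.runs))
        n_deep = sm.total_sum_normalize(sm.rollup_protein_intensity(deep.fragments, deep.runs))
    a = n_flat.data.to_numpy() / n_flat.data.to_numpy().sum()
    b = n_deep.data.to_numpy() / n_deep.data.to_numpy().sum()
    np.testing.assert_allclose(a, b, rtol=1e-9)
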