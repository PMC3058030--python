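"""Data model: loading, validation, the inclusion filter, presence matrix."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metallomap.datamodel import (
    IntegrityError,
    SchemaError,
    ValidationError,
    build_presence_matrix,
    filter_proteins,
    load_experiment,
    write_experiment,
)
from metallomap.synth import SynthConfig, generate, write_dataset


def _load_from_dir(d):
    return load_experiment(d / "fractions.tsv", d / "metals.tsv", d / "observations.tsv")


def test_write_then_load_round_trips_byte_identically(tmp_path):
    result = generate(SynthConfig(seed=3, n_separations=2, fractions_per_separation=15,
                                  metals=("Fe", "Zn"), peaks_per_metal=1,
                                  planted_per_metal=2, n_background_proteins=5))
    d1 = tmp_path / "a"
    write_dataset(result, d1)
    exp = _load_from_dir(d1)
    d2 = tmp_path / "b"
    write_experiment(exp, d2)
    for name in ("fractions.tsv", "metals.tsv", "observations.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def _write_tables(tmp_path, fractions, metals, observations):
    paths = {}
    for name, df in (("fractions", fractions), ("metals", metals), ("observations", observations)):
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


@pytest.fixture()
def valid_tables():
    fractions = pd.DataFrame(
        {
            "fraction_id": ["F1", "F2", "F3"],
            "separation_id": "S1",
            "order_index": [0, 1, 2],
            "parent_fraction_id": ".",
            "level": 1,
        }
    )
    metals = pd.DataFrame(
        {"fraction_id": ["F1", "F2"], "metal": "Ni", "replicate": 1, "concentration": [1.0, 2.0]}
    )
    observations = pd.DataFrame(
        {"fraction_id": ["F1", "F2"], "protein_id": ["PF0001", "PF0002"], "peptide_count": [3, 2]}
    )
    return fractions, metals, observations


def test_missing_column_is_a_schema_error_naming_it(tmp_path, valid_tables):
    fractions, metals, observations = valid_tables
    paths = _write_tables(tmp_path, fractions, metals.drop(columns=["replicate"]), observations)
    with pytest.raises(SchemaError, match="replicate"):
        load_experiment(paths["fractions"], paths["metals"], paths["observations"])


def test_dangling_fraction_reference_names_the_offender(tmp_path, valid_tables):
    fractions, metals, observations = valid_tables
    metals.loc[0, "fraction_id"] = "FX"
    paths = _write_tables(tmp_path, fractions, metals, observations)
    with pytest.raises(IntegrityError, match="FX"):
        load_experiment(paths["fractions"], paths["metals"], paths["observations"])


@pytest.mark.parametrize(
    "mutate, error, match",
    [
        (lambda f, m, o: m.__setitem__("concentration", [-1.0, 2.0]), ValidationError, "negative"),
        (lambda f, m, o: f.__setitem__("fraction_id", ["F1", "F1", "F3"]), ValidationError, "duplicate"),
        (lambda f, m, o: f.__setitem__("order_index", [0, 0, 2]), ValidationError, "order_index"),
        (lambda f, m, o: m.__setitem__("metal", "Xx"), ValidationError, "unknown metal"),
        (lambda f, m, o: o.__setitem__("peptide_count", [0, 2]), ValidationError, "peptide_count"),
        (lambda f, m, o: f.__setitem__("parent_fraction_id", ["F2", "F1", "."]), ValidationError, "cycle"),
    ],
)
def test_invariant_violations_raise(tmp_path, valid_tables, mutate, error, match):
    fractions, metals, observations = valid_tables
    mutate(fractions, metals, observations)
    paths = _write_tables(tmp_path, fractions, metals, observations)
    with pytest.raises(error, match=match):
        load_experiment(paths["fractions"], paths["metals"], paths["observations"])


def test_empty_observations_file_is_a_valid_zero_protein_bundle(tmp_path, valid_tables):
    fractions, metals, observations = valid_tables
    paths = _write_tables(tmp_path, fractions, metals, observations.iloc[:0])
    exp = load_experiment(paths["fractions"], paths["metals"], paths["observations"])
    assert len(exp.observations) == 0
    matrix = build_presence_matrix(exp.observations, exp.fractions)
    assert matrix.shape == (0, 3)


OBS = pd.DataFrame(
    {
        "fraction_id": ["F1"] * 2 + [f"F{i}" for i in range(1, 12)],
        "protein_id": ["A", "B"] + ["C"] * 11,
        "peptide_count": [1, 5] + [5] + [1] * 10,
    }
)


@pytest.mark.parametrize(
    "min_peptides, expected_proteins, expected_rows",
    [
        (2, {"B", "C"}, 12),  # A seen only as 1 peptide: removed entirely
        (1, {"A", "B", "C"}, 13),  # identity
        (5, {"B", "C"}, 12),  # one confident fraction rescues all 11 of C's rows
        (6, set(), 0),
    ],
)
def test_inclusion_filter_is_dataset_wide_on_max_peptides(min_peptides, expected_proteins, expected_rows):
    out = filter_proteins(OBS, min_peptides=min_peptides)
    assert set(out["protein_id"]) == expected_proteins
    assert len(out) == expected_rows


@given(
    counts=st.lists(st.tuples(st.integers(0, 5), st.integers(0, 4), st.integers(1, 6)), max_size=30),
    lo=st.integers(1, 4),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_filter_is_idempotent_and_monotone(counts, lo):
    obs = pd.DataFrame(
        [{"fraction_id": f"F{f}", "protein_id": f"P{p}", "peptide_count": c} for p, f, c in counts]
    ).drop_duplicates(subset=["fraction_id", "protein_id"])
    if not len(obs):
        obs = OBS.iloc[:0]
    once = filter_proteins(obs, min_peptides=lo)
    assert filter_proteins(once, min_peptides=lo).equals(once)
    stricter = filter_proteins(obs, min_peptides=lo + 1)
    assert set(stricter["protein_id"]) <= set(once["protein_id"])


def test_presence_matrix_cells_equal_distinct_pairs_and_duplicates_collapse(tiny_fractions):
    obs = pd.DataFrame(
        {
            "fraction_id": ["F00", "F00", "F03", "F05"],
            "protein_id": ["A", "A", "A", "B"],
            "peptide_count": [1, 2, 1, 4],
        }
    )
    matrix = build_presence_matrix(obs, tiny_fractions)
    assert matrix.shape == (2, 20)
    assert int(matrix.to_numpy().sum()) == 3  # distinct (protein, fraction) pairs
    assert bool(matrix.loc["A", "F00"]) and bool(matrix.loc["A", "F03"]) and bool(matrix.loc["B", "F05"])
    assert list(matrix.index) == ["A", "B"]  # lexicographic rows
    assert list(matrix.columns) == list(tiny_fractions["fraction_id"])  # elution order


def test_presence_matrix_rejects_unknown_fractions(tiny_fractions):
    obs = pd.DataFrame({"fraction_id": ["FXX"], "protein_id": ["A"], "peptide_count": [2]})
    with pytest.raises(IntegrityError, match="FXX"):
        build_presence_matrix(obs, tiny_fractions)
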