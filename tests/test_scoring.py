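"""Reward stack: fragment scores, reward maps, final score with exclusions.

The synthetic-accessibility and natural-product scores are cross-checked
against the independently published scorer implementations distributed with
RDKit, using the published contribution tables.
"""


import numpy as np
import pytest

from flavorgen.errors import ContractError, FormatError, ValidityError
from flavorgen.graphs import MolecularGraph, parse_smiles
from flavorgen.model import SampledMolecule
from flavorgen.scoring import (
    FragmentScoreTable,
    final_scores,
    fixture_tables,
    load_reference_np_table,
    load_reference_sa_table,
    np_reward,
    np_score,
    optimality,
    read_table,
    sa_reward,
    sa_score,
    scores_to_frame,
    size_reward,
    write_table,
)


def _sampled(smiles, terminated=True, valid=True):
    return SampledMolecule(parse_smiles(smiles), [], -1.0, terminated, valid)


class TestTables:
    def test_read_write_round_trip(self, tmp_path):
        table = FragmentScoreTable({1: 0.5, 99: -1.25}, default=-4.0)
        write_table(table, tmp_path / "t.txt")
        back = read_table(tmp_path / "t.txt", default=-4.0)
        assert back.contributions == table.contributions

    def test_gzip_tolerated(self, tmp_path):
        import gzip

        with gzip.open(tmp_path / "t.gz", "wt") as fh:
            fh.write("# comment\n7 1.5\n8 -2\n")
        table = read_table(tmp_path / "t.gz")
        assert table.contributions == {7: 1.5, 8: -2.0}

    def test_malformed_line_raises(self, tmp_path):
        (tmp_path / "bad.txt").write_text("1 2 3\n")
        with pytest.raises(FormatError):
            read_table(tmp_path / "bad.txt")

    def test_non_finite_contribution_rejected(self):
        with pytest.raises(FormatError):
            FragmentScoreTable({1: float("nan")})

    def test_fixture_tables_cover_fixture_fragments(self, records200,
                                                    score_tables):
        sa_table, np_table = score_tables
        assert len(sa_table.contributions) > 50
        assert sa_table.default == -4.0 and np_table.default == 0.0


class TestSaScore:
    def test_range_on_fixture_set(self, records200, score_tables):
        sa_table, _ = score_tables
        values = [sa_score(parse_smiles(r.smiles), sa_table)
                  for r in records200]
        assert all(1.0 <= v <= 10.0 for v in values)

    def test_uniform_fragment_contribution_is_mean(self):
        # a long chain whose every fragment maps to the same value v: the
        # fragment term is exactly v, so two tables differing by dv shift
        # the raw score by dv and the final score by dv * 9 / 6.5
        g = parse_smiles("CCCCCCCC")
        from flavorgen.scoring import _fragment_counts, _to_rdkit

        frags = _fragment_counts(_to_rdkit(g))
        lo = sa_score(g, FragmentScoreTable({k: 1.0 for k in frags}))
        hi = sa_score(g, FragmentScoreTable({k: 2.0 for k in frags}))
        assert lo - hi == pytest.approx(9.0 / 6.5, rel=1e-9)

    def test_huge_negative_contributions_clamp_to_ten(self):
        g = parse_smiles("CCCCCO")
        table = FragmentScoreTable({}, default=-1000.0)
        assert sa_score(g, table) == 10.0

    def test_invalid_graph_rejected(self):
        with pytest.raises(ValidityError):
            sa_score(MolecularGraph(), FragmentScoreTable({}))

    def test_matches_published_scorer_on_reference_table(self, records200):
        import sys

        from rdkit import Chem, RDConfig

        sys.path.append(str(__import__("pathlib").Path(
            RDConfig.RDContribDir) / "SA_Score"))
        sascorer = pytest.importorskip("sascorer")

        table = load_reference_sa_table()
        checked = 0
        for rec in records200:
            mol = Chem.MolFromSmiles(rec.smiles)
            if Chem.FindMolChiralCenters(mol, includeUnassigned=True):
                continue  # stereo term is out of scope here
            mine = sa_score(parse_smiles(rec.smiles), table)
            theirs = sascorer.calculateScore(mol)
            assert mine == pytest.approx(theirs, abs=1e-8)
            checked += 1
            if checked >= 15:
                break
        assert checked >= 10


class TestNpScore:
    def test_range_on_fixture_set(self, records200, score_tables):
        _, np_table = score_tables
        values = [np_score(parse_smiles(r.smiles), np_table)
                  for r in records200]
        assert all(-5.0 <= v <= 5.0 for v in values)

    def test_all_zero_table_gives_zero(self):
        assert np_score(parse_smiles("CCCCCO"), FragmentScoreTable({})) == 0.0

    def test_linear_below_compression(self):
        g = parse_smiles("CCO")
        from flavorgen.scoring import _fragment_counts, _to_rdkit

        frags = _fragment_counts(_to_rdkit(g))
        t1 = FragmentScoreTable({k: 0.5 for k in frags})
        t2 = FragmentScoreTable({k: 1.0 for k in frags})
        assert np_score(g, t2) == pytest.approx(2 * np_score(g, t1), rel=1e-9)

    def test_matches_published_scorer_on_reference_table(self, records200):
        import sys

        from rdkit import Chem, RDConfig

        sys.path.append(str(__import__("pathlib").Path(
            RDConfig.RDContribDir) / "NP_Score"))
        npscorer = pytest.importorskip("npscorer")

        table = load_reference_np_table()
        model = npscorer.readNPModel()
        for rec in records200[:25]:
            mine = np_score(parse_smiles(rec.smiles), table)
            theirs = npscorer.scoreMol(Chem.MolFromSmiles(rec.smiles), model)
            assert mine == pytest.approx(theirs, abs=1e-8)


class TestRewards:
    @pytest.mark.parametrize("graph_smiles, max_nodes, expected", [
        ("CCCCCO", 13, 1),          # pentan-1-ol fits the target size
        ("C" * 14, 13, 0),          # 14-carbon chain exceeds the cap
        ("C", 13, 1),
    ])
    def test_size_reward_rule(self, graph_smiles, max_nodes, expected):
        assert size_reward(parse_smiles(graph_smiles), max_nodes) == expected

    def test_size_reward_empty_graph_is_zero(self):
        assert size_reward(MolecularGraph(), 13) == 0

    @pytest.mark.parametrize("sa, expected", [(1.0, 1.0), (10.0, 0.0),
                                              (5.5, 0.5)])
    def test_sa_reward_affine_map(self, sa, expected):
        assert sa_reward(sa) == pytest.approx(expected)

    @pytest.mark.parametrize("np_val, expected", [(5.0, 1.0), (-5.0, 0.0),
                                                  (0.0, 0.5)])
    def test_np_reward_affine_map(self, np_val, expected):
        assert np_reward(np_val) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_call", [
        lambda: sa_reward(0.5), lambda: sa_reward(10.5),
        lambda: np_reward(-6.0), lambda: np_reward(5.1),
    ])
    def test_out_of_range_rejected(self, bad_call):
        with pytest.raises(ContractError):
            bad_call()


class TestFinalScores:
    def test_duplicate_excluded_second_only(self, score_tables):
        sa_table, np_table = score_tables
        out = final_scores([_sampled("CCCCCO"), _sampled("OCCCCC")],
                           sa_table, np_table, 13)
        assert not out[0].excluded
        assert out[1].excluded and out[1].exclusion_reason == "duplicate"
        assert out[1].final_score == 0.0

    def test_invalid_and_unfinished_excluded(self, score_tables):
        sa_table, np_table = score_tables
        out = final_scores(
            [_sampled("CCO", valid=False), _sampled("CCC", terminated=False)],
            sa_table, np_table, 13)
        assert [b.exclusion_reason for b in out] == ["invalid", "unfinished"]
        assert all(b.final_score == 0.0 for b in out)

    def test_equal_weight_mean(self, score_tables):
        sa_table, np_table = score_tables
        out = final_scores([_sampled("CCCCCO")], sa_table, np_table, 13)[0]
        expected = (out.sa_reward + out.np_reward + out.size_reward) / 3.0
        assert out.final_score == pytest.approx(expected)
        assert 0.0 <= out.final_score <= 1.0

    def test_batch_scores_bounded(self, records200, score_tables):
        sa_table, np_table = score_tables
        batch = [_sampled(r.smiles) for r in records200[:50]]
        out = final_scores(batch, sa_table, np_table, 16)
        assert all(0.0 <= b.final_score <= 1.0 for b in out)
        assert np.mean([b.final_score for b in out]) <= 1.0

    def test_scores_invariant_under_atom_reordering(self, score_tables):
        sa_table, np_table = score_tables
        a = parse_smiles("CC(=O)CCO")
        b = parse_smiles("OCCC(C)=O")  # same molecule, different atom order
        assert sa_score(a, sa_table) == pytest.approx(sa_score(b, sa_table))
        assert np_score(a, np_table) == pytest.approx(np_score(b, np_table))

    def test_frame_export_columns(self, score_tables):
        sa_table, np_table = score_tables
        frame = scores_to_frame(final_scores([_sampled("CCO")],
                                             sa_table, np_table, 13))
        assert list(frame.columns) == ["smiles", "sa", "np", "size", "final",
                                       "excluded_reason"]


class TestOptimality:
    @pytest.mark.parametrize("sa, np_val, expected", [
        (2.1, 1.5, True),
        (3.0, 1.5, False),   # strict inequality on SA
        (2.1, 0.0, False),   # strict inequality on NP
    ])
    def test_rule(self, sa, np_val, expected):
        from flavorgen.scoring import ScoreBreakdown

        b = ScoreBreakdown("C", sa_score=sa, np_score=np_val)
        assert optimality(b) is expected

    def test_excluded_rejected(self):
        from flavorgen.scoring import ScoreBreakdown

        with pytest.raises(ContractError):
            optimality(ScoreBreakdown(None, excluded=True))
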