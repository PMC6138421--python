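"""End-to-end protocol: encrypted vs plaintext equivalence, file-based
exchange, reproducibility, CLI."""

import random

import pytest
from click.testing import CliRunner

from sigdb.cli import cli
from sigdb.protocol import (
    ProtocolConfig,
    run_exchange,
    run_protocol,
    run_protocol_plaintext,
)
from sigdb.sequences import write_fasta
from sigdb.synthetic import prefix_query, random_genome

CFG = dict(k=8, key_size=512, truncate_len=150, hash_seed=3)


@pytest.fixture(scope="module")
def small_world():
    query = random_genome(150, seed=1, id="query")
    db = [
        random_genome(150, seed=1, id="match"),  # identical to query
        random_genome(150, seed=2, id="other1"),
        random_genome(120, seed=3, id="other2"),
        prefix_query(random_genome(150, seed=1, id="match"), 100),
    ]
    return query, db


class TestRunProtocol:
    def test_encrypted_equals_plaintext_path_exactly(self, small_world):
        query, db = small_world
        enc = run_protocol(query, db, ProtocolConfig(**CFG))
        plain = run_protocol_plaintext(query, db, ProtocolConfig(**CFG))
        assert [
            (r.entry_id, r.intersection, r.db_magnitude, r.iou, r.ioq, r.iod)
            for r in enc
        ] == [
            (r.entry_id, r.intersection, r.db_magnitude, r.iou, r.ioq, r.iod)
            for r in plain
        ]

    def test_identical_entry_tops_iou_ranking_with_one(self, small_world):
        query, db = small_world
        results = run_protocol(query, db, ProtocolConfig(**CFG))
        best = max(results, key=lambda r: r.iou)
        assert best.entry_id == "match"
        assert (best.iou, best.ioq, best.iod) == (1.0, 1.0, 1.0)

    def test_result_count_matches_db_size(self, small_world):
        query, db = small_world
        assert len(run_protocol_plaintext(query, db)) == len(db)


class TestRunExchange:
    def make_fastas(self, tmp_path, query, db):
        qp, dp = tmp_path / "q.fasta", tmp_path / "db.fasta"
        write_fasta(qp, [query])
        write_fasta(dp, db)
        return qp, dp

    def test_artifacts_and_results_written(self, tmp_path, small_world):
        query, db = small_world
        qp, dp = self.make_fastas(tmp_path, query, db)
        tsv = run_exchange(qp, dp, ProtocolConfig(**CFG), outdir=tmp_path / "run")
        for name in (
            "public_key.json", "private_key.json", "constructor.json",
            "encrypted_query.json", "query_state.json", "score_pairs.json",
        ):
            assert (tmp_path / "run" / name).exists()
        lines = tsv.read_text().splitlines()
        assert lines[0].split("\t") == [
            "entry_id", "db_magnitude", "intersection", "iou", "ioq", "iod"
        ]
        assert len(lines) == 1 + len(db)

    def test_fixture_mode_rerun_is_byte_identical(self, tmp_path, small_world):
        query, db = small_world
        qp, dp = self.make_fastas(tmp_path, query, db)
        outs = []
        for sub in ("r1", "r2"):
            cfg = ProtocolConfig(rng=random.Random(99), **CFG)
            outs.append(run_exchange(qp, dp, cfg, outdir=tmp_path / sub).read_bytes())
        assert outs[0] == outs[1]

    def test_owner_artifacts_never_contain_query_plaintext(self, tmp_path, small_world):
        query, db = small_world
        qp, dp = self.make_fastas(tmp_path, query, db)
        run_exchange(qp, dp, ProtocolConfig(**CFG), outdir=tmp_path / "leak")
        from sigdb.lsh import build_lsh
        from sigdb.serialization import constructor_from_dict, load_json

        c = constructor_from_dict(load_json(tmp_path / "leak" / "constructor.json"))
        bits = "".join(
            "1" if b else "0" for b in build_lsh(query, c).bits
        )
        for owner_file in ("encrypted_query.json", "constructor.json"):
            payload = (tmp_path / "leak" / owner_file).read_text()
            assert query.bases not in payload
            assert bits not in payload
            assert "query_magnitude" not in payload


class TestCli:
    def test_run_subcommand_end_to_end(self, tmp_path):
        query = random_genome(100, seed=5, id="q")
        db = [random_genome(100, seed=5, id="hit"), random_genome(100, seed=6, id="miss")]
        qp, dp = tmp_path / "q.fasta", tmp_path / "db.fasta"
        write_fasta(qp, [query])
        write_fasta(dp, db)
        runner = CliRunner()
        result = runner.invoke(
            cli,
            ["run", str(qp), str(dp), "--key-size", "512", "--truncate-len", "100",
             "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        rows = (tmp_path / "out" / "results.tsv").read_text().splitlines()[1:]
        scores = {r.split("\t")[0]: float(r.split("\t")[3]) for r in rows}
        assert scores["hit"] == 1.0
        assert scores["miss"] < 0.5

    def test_staged_subcommands_match_run(self, tmp_path):
        query = random_genome(80, seed=7, id="q")
        db = [random_genome(80, seed=7, id="hit")]
        qp, dp = tmp_path / "q.fasta", tmp_path / "db.fasta"
        write_fasta(qp, [query])
        write_fasta(dp, db)
        runner = CliRunner()
        out = tmp_path / "stage"
        steps = [
            ["keygen", "--key-size", "512", "--out", str(out)],
            ["build-query", str(qp), "--public-key", str(out / "public_key.json"),
             "--max-db-len", "80", "--out", str(out)],
            ["score", str(dp), "--encrypted-query", str(out / "encrypted_query.json"),
             "--out", str(out / "score_pairs.json")],
            ["decrypt-scores", str(out / "score_pairs.json"),
             "--private-key", str(out / "private_key.json"),
             "--query-state", str(out / "query_state.json"),
             "--out", str(out / "results.tsv")],
        ]
        for step in steps:
            result = runner.invoke(cli, step)
            assert result.exit_code == 0, (step, result.output)
        row = (out / "results.tsv").read_text().splitlines()[1].split("\t")
        assert row[0] == "hit"
        assert float(row[3]) == 1.0
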