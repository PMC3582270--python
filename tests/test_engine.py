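"""Rule-graph parsing, execution, resume, and the file-backed stores."""

import time

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spliceflow.engine import (
    DONE,
    ExecutionReport,
    ProjectConfig,
    ResultsStore,
    RuleGraph,
    StateStore,
    parse_template,
    run,
)

TEMPLATE = """\
# variables set at the top are substituted into commands
BIN = /opt/bin
LOG = logs

start:
    true

preprocess: start
    $BIN/preprocess.RNAseq.pl
    mv preprocess.RNAseq.log $LOG
"""


def test_parse_template_preprocess_block(tmp_path):
    p = tmp_path / "t.tmpl"
    p.write_text(TEMPLATE)
    g = parse_template(str(p))
    step = g.steps["preprocess"]
    assert step.dependencies == ["start"]
    assert step.commands == [
        "/opt/bin/preprocess.RNAseq.pl",
        "mv preprocess.RNAseq.log logs",
    ]


def test_self_dependency_is_a_cycle_error(tmp_path):
    p = tmp_path / "t.tmpl"
    p.write_text("a: a\n    true\n")
    with pytest.raises(ValueError, match="cycle"):
        parse_template(str(p))


def test_unknown_dependency_error(tmp_path):
    p = tmp_path / "t.tmpl"
    p.write_text("a: ghost\n    true\n")
    with pytest.raises(ValueError, match="ghost"):
        parse_template(str(p))


def test_random_dag_executes_in_topological_order(tmp_path):
    rng = np.random.default_rng(2)
    g = RuleGraph()
    order_log = []
    names = [f"s{i}" for i in range(8)]
    edges = []
    for i, name in enumerate(names):
        deps = [names[j] for j in range(i) if rng.random() < 0.4]
        edges += [(d, name) for d in deps]
        g.add(name, deps, [lambda n=name: order_log.append(n)])
    state = StateStore(str(tmp_path / "state.json"))
    run(g, names[-1], state, workdir=str(tmp_path))
    executed_pos = {n: i for i, n in enumerate(order_log)}
    needed = nx.ancestors(g.to_networkx(), names[-1]) | {names[-1]}
    for u, v in edges:
        if u in needed and v in needed:
            assert executed_pos[u] < executed_pos[v]


def _diamond(tmp_path, sink_cmds=None, fail_step=None):
    g = RuleGraph()
    log = []

    def cmd(name):
        if name == fail_step:
            return lambda: (_ for _ in ()).throw(RuntimeError("boom"))
        return lambda: log.append(name)

    g.add("start", [], [cmd("start")])
    g.add("left", ["start"], [cmd("left")])
    g.add("right", ["start"], [cmd("right")])
    g.add("sink", ["left", "right"], sink_cmds or [cmd("sink")])
    return g, log


def test_fresh_run_executes_all_ancestors(tmp_path):
    g, log = _diamond(tmp_path)
    state = StateStore(str(tmp_path / "s.json"))
    report = run(g, "sink", state, workdir=str(tmp_path))
    assert set(report.executed) == {"start", "left", "right", "sink"}
    assert report.ok


def test_rerun_executes_zero_steps(tmp_path):
    g, log = _diamond(tmp_path)
    state = StateStore(str(tmp_path / "s.json"))
    run(g, "sink", state, workdir=str(tmp_path))
    report2 = run(g, "sink", state, workdir=str(tmp_path))
    assert report2.executed == []
    assert set(report2.skipped) == {"start", "left", "right", "sink"}


def test_subset_target_never_touches_non_ancestors(tmp_path):
    g, log = _diamond(tmp_path)
    state = StateStore(str(tmp_path / "s.json"))
    report = run(g, "left", state, workdir=str(tmp_path))
    assert set(report.executed) == {"start", "left"}
    assert state.get("right")["status"] != DONE
    assert state.get("sink")["status"] != DONE


def test_failure_blocks_dependents_but_not_siblings(tmp_path):
    g, log = _diamond(tmp_path, fail_step="left")
    state = StateStore(str(tmp_path / "s.json"))
    report = run(g, "sink", state, workdir=str(tmp_path))
    assert report.failed == ["left"]
    assert "sink" in report.blocked
    assert "right" in report.executed  # independent branch completed
    assert not report.ok


def test_resume_after_interruption(tmp_path):
    """Stop after the mapping-like middle step; the rerun skips completed
    work and finishes the rest."""
    g, log = _diamond(tmp_path)
    state = StateStore(str(tmp_path / "s.json"))
    run(g, "left", state, workdir=str(tmp_path))  # "interrupted" here
    report = run(g, "sink", state, workdir=str(tmp_path))
    assert "left" not in report.executed and "start" not in report.executed
    assert {"right", "sink"} <= set(report.executed)


def test_stale_step_reruns_when_ancestor_is_newer(tmp_path):
    g, log = _diamond(tmp_path)
    state = StateStore(str(tmp_path / "s.json"))
    run(g, "sink", state, workdir=str(tmp_path))
    state.set("start", DONE, timestamp=time.time() + 100)  # ancestor newer
    report = run(g, "sink", state, workdir=str(tmp_path))
    assert {"left", "right", "sink"} <= set(report.executed)


def test_state_survives_restart(tmp_path):
    path = str(tmp_path / "s.json")
    StateStore(path).set("map", DONE)
    fresh = StateStore(path)
    assert fresh.get("map")["status"] == DONE
    assert fresh.get("map")["timestamp"] is not None


def test_results_store_round_trip_and_unknown_dataset(tmp_path):
    store = ResultsStore(str(tmp_path))
    store.add_dataset("d1")
    df = pd.DataFrame({"a": [1, 2], "b": ["x", "y"]})
    store.put("t", df, dataset="d1")
    back = store.get("t", dataset="d1")
    pd.testing.assert_frame_equal(df, back)
    with pytest.raises(KeyError):
        store.put("t", df, dataset="ghost")
    # common store needs no dataset registration
    store.put("shared", df)
    assert store.has("shared")


def test_junction_library_cached_across_datasets(tmp_path, tiny):
    from spliceflow.pipeline import get_junction_library

    genome, model = tiny
    store = ResultsStore(str(tmp_path))
    lib1 = get_junction_library(store, model, genome, flank=15)
    assert store.has("junction_library_flank15")
    lib2 = get_junction_library(store, model, genome, flank=15)  # cache hit
    assert {j.key for j in lib1} == {j.key for j in lib2}
    c1 = {cid: c.sequence for cid, c in lib1.contigs.items()}
    c2 = {cid: c.sequence for cid, c in lib2.contigs.items()}
    assert c1 == c2


def test_shell_commands_and_logs(tmp_path):
    p = tmp_path / "t.tmpl"
    p.write_text("OUT = marker.txt\n\nstart:\n    true\n\nwrite: start\n    echo hello > $OUT\n")
    g = parse_template(str(p))
    state = StateStore(str(tmp_path / "s.json"))
    report = run(g, "write", state, workdir=str(tmp_path))
    assert report.ok
    assert (tmp_path / "marker.txt").read_text().strip() == "hello"
    assert (tmp_path / "logs" / "write.log").exists()


def test_project_config_validation(tmp_path):
    cfg = ProjectConfig(genome=str(tmp_path / "missing.fa"), annotation="x",
                        results_dir="r", datasets={})
    with pytest.raises(FileNotFoundError):
        cfg.validate()
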