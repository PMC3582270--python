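"""Rule-based pipeline execution with timestamped resume.

A template file (Makefile-like) declares named steps, their prerequisite
steps and the commands each runs; variables such as BIN and LOG declared at
the top of the file are substituted into commands.  The engine builds the
dependency graph, validates it (acyclic, all dependencies defined), and
executes — in topological order — exactly the ancestors of the requested
target whose state is not already done.  Completion timestamps are persisted,
so an interrupted run resumes where it left off; a step also re-runs when any
ancestor finished after it (Make semantics).  A failed step stops its
dependents but independent branches still complete.

Results live in two file-backed stores: ``common`` for annotation-derived
shared data (the junction library cache, indices, metadata) and ``results``
for per-dataset tables and step states — the two-database split, kept logical
rather than relational.
"""

from __future__ import annotations

import json
import os
import shlex
import string
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Union

import networkx as nx
import pandas as pd
import yaml

Command = Union[str, Callable[[], None]]

PENDING, RUNNING, DONE, FAILED = "pending", "running", "done", "failed"


@dataclass
class Step:
    name: str
    dependencies: List[str]
    commands: List[Command]


@dataclass
class RuleGraph:
    steps: Dict[str, Step] = field(default_factory=dict)
    variables: Dict[str, str] = field(default_factory=dict)

    def add(self, name: str, dependencies: List[str], commands: List[Command]) -> None:
        if name in self.steps:
            raise ValueError(f"duplicate step {name!r}")
        self.steps[name] = Step(name, list(dependencies), list(commands))

    def validate(self) -> None:
        for step in self.steps.values():
            for dep in step.dependencies:
                if dep not in self.steps:
                    raise ValueError(
                        f"step {step.name!r} depends on unknown step {dep!r}"
                    )
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join(str(u) for u, _ in nx.find_cycle(g))
            raise ValueError(f"dependency cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.steps)
        for step in self.steps.values():
            for dep in step.dependencies:
                g.add_edge(dep, step.name)
        return g

    def execution_order(self, target: str) -> List[str]:
        """Ancestors of target plus target, in a valid topological order."""
        if target not in self.steps:
            raise KeyError(f"unknown target step {target!r}")
        g = self.to_networkx()
        needed = nx.ancestors(g, target) | {target}
        sub = g.subgraph(needed)
        return [n for n in nx.lexicographical_topological_sort(sub)]


def parse_template(path: str) -> RuleGraph:
    """Parse a rule template.

    Syntax: ``NAME = value`` variable lines at the top; ``step: dep1 dep2``
    headers; indented lines below a header are that step's commands, with
    ``$VAR``/``${VAR}`` substituted from the declared variables.
    """
    graph = RuleGraph()
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line[0] not in (" ", "\t"):
                if "=" in line and ":" not in line.split("=")[0]:
                    name, _, value = line.partition("=")
                    graph.variables[name.strip()] = value.strip()
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'step: deps' header")
                name, _, deps = line.partition(":")
                name = name.strip()
                graph.add(name, deps.split(), [])
                current = name
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: command before any step header")
                cmd = string.Template(line.strip()).safe_substitute(graph.variables)
                graph.steps[current].commands.append(cmd)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# State and results persistence


class StateStore:
    """JSON-backed per-step states; survives process restarts."""

    def __init__(self, path: str):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._states: Dict[str, dict] = {}
        if self.path.exists():
            self._states = json.loads(self.path.read_text())

    def get(self, step: str) -> dict:
        return self._states.get(step, {"status": PENDING, "timestamp": None, "log": None})

    def set(self, step: str, status: str, timestamp: Optional[float] = None,
            log: Optional[str] = None, provenance: str = "run") -> None:
        if status == DONE and timestamp is None:
            timestamp = time.time()
        self._states[step] = {
            "status": status,
            "timestamp": timestamp,
            "log": log,
            "provenance": provenance,
        }
        self._flush()

    def _flush(self) -> None:
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self._states, indent=1))
        os.replace(tmp, self.path)

    def mark_external(self, step: str) -> None:
        """Short-circuit a step (e.g. mapping when prealigned input is given)."""
        self.set(step, DONE, provenance="external")


class ResultsStore:
    """Two logical stores of TSV tables: ``common`` (shared, annotation-derived)
    and ``results`` (one directory per dataset)."""

    def __init__(self, base: str):
        self.base = Path(base)
        (self.base / "common").mkdir(parents=True, exist_ok=True)
        (self.base / "results").mkdir(parents=True, exist_ok=True)

    def add_dataset(self, dataset: str) -> Path:
        d = self.base / "results" / dataset
        d.mkdir(parents=True, exist_ok=True)
        return d

    def dataset_dir(self, dataset: str) -> Path:
        d = self.base / "results" / dataset
        if not d.is_dir():
            raise KeyError(f"unknown dataset {dataset!r}; call add_dataset first")
        return d

    def _table_path(self, dataset: Optional[str], table: str) -> Path:
        if dataset is None:
            return self.base / "common" / f"{table}.tsv"
        return self.dataset_dir(dataset) / f"{table}.tsv"

    def put(self, table: str, rows: pd.DataFrame, dataset: Optional[str] = None) -> Path:
        path = self._table_path(dataset, table)
        rows.to_csv(path, sep="\t", index=False)
        return path

    def get(self, table: str, dataset: Optional[str] = None) -> pd.DataFrame:
        path = self._table_path(dataset, table)
        if not path.exists():
            raise KeyError(f"no table {table!r} for dataset {dataset!r}")
        return pd.read_csv(path, sep="\t")

    def has(self, table: str, dataset: Optional[str] = None) -> bool:
        try:
            return self._table_path(dataset, table).exists()
        except KeyError:
            return False


# ---------------------------------------------------------------------------
# Execution


@dataclass
class ExecutionReport:
    target: str
    executed: List[str] = field(default_factory=list)
    skipped: List[str] = field(default_factory=list)
    failed: List[str] = field(default_factory=list)
    blocked: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed and not self.blocked


def run(
    graph: RuleGraph,
    target: str,
    state: StateStore,
    workdir: str = ".",
    log_dir: Optional[str] = None,
) -> ExecutionReport:
    """Execute the steps needed to reach ``target``.

    Steps already done (and not stale relative to their ancestors) are
    skipped; a failing command marks its step failed and blocks dependents,
    while independent branches still run.  Shell commands execute in
    ``workdir`` with per-step logs.
    """
    graph.validate()
    order = graph.execution_order(target)
    logs = Path(log_dir) if log_dir else Path(workdir) / "logs"
    logs.mkdir(parents=True, exist_ok=True)
    report = ExecutionReport(target=target)
    dead: set = set()

    for name in order:
        step = graph.steps[name]
        if any(d in dead for d in step.dependencies):
            dead.add(name)
            report.blocked.append(name)
            continue
        st = state.get(name)
        dep_times = [
            state.get(d)["timestamp"] or 0.0 for d in step.dependencies
        ]
        stale = st["status"] == DONE and dep_times and st["timestamp"] is not None \
            and max(dep_times) > st["timestamp"]
        if st["status"] == DONE and not stale:
            report.skipped.append(name)
            continue
        log_path = logs / f"{name}.log"
        state.set(name, RUNNING, log=str(log_path))
        try:
            with open(log_path, "a") as log:
                for cmd in step.commands:
                    if callable(cmd):
                        log.write(f"[python] {getattr(cmd, '__name__', repr(cmd))}\n")
                        log.flush()
                        cmd()
                    else:
                        log.write(f"[shell] {cmd}\n")
                        log.flush()
                        subprocess.run(
                            cmd, shell=True, cwd=workdir, stdout=log,
                            stderr=subprocess.STDOUT, check=True,
                        )
        except Exception as exc:  # noqa: BLE001 — step failure is data, not a crash
            state.set(name, FAILED, log=str(log_path))
            report.failed.append(name)
            dead.add(name)
            with open(log_path, "a") as log:
                log.write(f"[failed] {exc}\n")
            continue
        state.set(name, DONE, log=str(log_path))
        report.executed.append(name)
    return report


# ---------------------------------------------------------------------------
# Project configuration


@dataclass
class DatasetConfig:
    name: str
    reads: List[str] = field(default_factory=list)  # 1 file, or 2 for paired
    paired: bool = False
    stranded: bool = False
    format: str = "auto"
    alignments: Optional[str] = None  # prealigned SAM/BAM short-circuits mapping


@dataclass
class ProjectConfig:
    genome: str
    annotation: str
    results_dir: str
    datasets: Dict[str, DatasetConfig]
    params: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str) -> "ProjectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        datasets = {}
        for name, d in raw.get("datasets", {}).items():
            datasets[name] = DatasetConfig(
                name=name,
                reads=d.get("reads", []),
                paired=bool(d.get("paired", False)),
                stranded=bool(d.get("stranded", False)),
                format=d.get("format", "auto"),
                alignments=d.get("alignments"),
            )
        cfg = cls(
            genome=raw["genome"],
            annotation=raw["annotation"],
            results_dir=raw.get("results_dir", "results"),
            datasets=datasets,
            params=raw.get("params", {}),
        )
        return cfg

    def validate(self) -> None:
        for p in [self.genome, self.annotation]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        for ds in self.datasets.values():
            for f in ds.reads:
                if not os.path.exists(f):
                    raise FileNotFoundError(f)
            if ds.paired and len(ds.reads) not in (1, 2):
                raise ValueError(
                    f"dataset {ds.name}: paired data need one interleaved or two files"
                )
            if ds.alignments and not os.path.exists(ds.alignments):
                raise FileNotFoundError(ds.alignments)
        trim_step = self.params.get("trim_step", 10)
        if trim_step <= 0:
            raise ValueError("trim_step must be positive")


DEFAULT_STEPS = ("start", "qc", "map", "quant", "discover")


def default_template_text(bin_name: str = "spliceflow") -> str:
    """The shipped, user-editable default template: each analysis step is one
    CLI invocation; edit, add or remove steps freely."""
    return f"""\
# Default pipeline template. Variables below are substituted into commands.
BIN = {bin_name}
CONFIG = project.yml
DATASET = default

start:
    true

qc: start
    $BIN qc --config $CONFIG --dataset $DATASET

map: qc
    $BIN map --config $CONFIG --dataset $DATASET

quant: map
    $BIN quant --config $CONFIG --dataset $DATASET

discover: quant
    $BIN discover --config $CONFIG --dataset $DATASET
"""
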