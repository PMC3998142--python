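"""Dependency-driven job engine with tiered master/worker execution.

Each analysis is a *job*: an ordered set of named steps wired by
dependencies (merging and branching both allowed).  Planning binds
chunkable steps to chunks of the deduplicated sequence set, producing
*step instances* — self-contained executable units.  A single master
dispatches ready instances onto a FIFO request queue; workers poll the
queue, execute, and report on a response channel (at-least-once
delivery; step outputs are written atomically to make re-execution
idempotent).

Two execution modes share the same plan and step functions:

* ``serial`` — in-process, deterministic topological order.
* ``multiprocess`` — OS-process workers.  The master spawns direct
  workers up to a limit; surplus demand is delegated to existing
  workers, which spawn a further tier of workers themselves (any
  number of tiers, bounded by policy).  Workers expire after an idle
  timeout; a dead worker's outstanding instances are re-queued and
  retried up to the retry limit.

Intermediate artifacts pass by path on a shared filesystem, not by
message payload; descriptors carry only names, chunk checksums and the
working directory.
"""

from __future__ import annotations

import json
import logging
import multiprocessing as mp
import os
import queue as queue_mod
import time
import traceback
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

STEP_KINDS = ("write_fasta", "run_analyzer_scan", "run_postprocess",
              "persist_matches")

PENDING, READY, DISPATCHED, DONE, FAILED = (
    "pending", "ready", "dispatched", "done", "failed")


class PlanningError(ValueError):
    pass


class ExecutionError(RuntimeError):
    def __init__(self, message: str, report: "ExecutionReport",
                 instance_id: Optional[str] = None,
                 diagnostics: Optional[str] = None):
        super().__init__(message)
        self.report = report
        self.instance_id = instance_id
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Step:
    name: str
    kind: str
    depends_on: frozenset = frozenset()
    chunkable: bool = True

    def __post_init__(self):
        if self.kind not in STEP_KINDS:
            raise ValueError(f"unknown step kind {self.kind!r}")


@dataclass
class Job:
    name: str
    steps: List[Step]

    def __post_init__(self):
        names = [s.name for s in self.steps]
        if len(names) != len(set(names)):
            raise ValueError(f"job {self.name}: duplicate step names")
        known = set(names)
        for s in self.steps:
            missing = s.depends_on - known
            if missing:
                raise ValueError(
                    f"job {self.name}: step {s.name} depends on unknown "
                    f"step(s) {sorted(missing)}")


@dataclass(frozen=True)
class ChunkSpec:
    chunk_index: int
    md5_list: Tuple[str, ...]


@dataclass
class StepInstance:
    """One step bound to one chunk (or to the whole set if the step is
    not chunkable).  State transitions: pending→ready→dispatched→
    (done|failed); failed re-enters ready while attempts < retry limit.
    """

    job_name: str
    step: Step
    chunk: Optional[ChunkSpec]
    deps: Tuple[str, ...] = ()
    state: str = PENDING
    attempts: int = 0
    n_chunks: int = 0  # total chunks in this job's plan (for fan-in steps)

    @property
    def id(self) -> str:
        if self.chunk is None:
            return f"{self.job_name}/{self.step.name}"
        return f"{self.job_name}/{self.step.name}#{self.chunk.chunk_index}"

    def sort_key(self):
        ci = self.chunk.chunk_index if self.chunk else -1
        return (self.job_name, self.step.name, ci)

    def descriptor(self) -> dict:
        """A self-contained work description: a worker needs only this
        plus the shared working directory."""
        return {
            "id": self.id,
            "job": self.job_name,
            "step": self.step.name,
            "kind": self.step.kind,
            "chunk_index": self.chunk.chunk_index if self.chunk else None,
            "md5s": list(self.chunk.md5_list) if self.chunk else [],
            "n_chunks": self.n_chunks,
        }


@dataclass
class WorkerPolicy:
    """Worker-management knobs (all positive)."""

    max_direct_workers: int = 4
    max_tiers: int = 3
    worker_lifetime: float = 5.0   # idle seconds before a worker expires
    retry_limit: int = 2           # attempts per step instance
    backlog_threshold: int = 1     # queue backlog that triggers spawning
    stall_timeout: float = 10.0    # re-queue outstanding work after silence

    def __post_init__(self):
        for name in ("max_direct_workers", "max_tiers", "retry_limit",
                     "backlog_threshold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.worker_lifetime <= 0 or self.stall_timeout <= 0:
            raise ValueError("timeouts must be positive")


@dataclass
class ExecutionReport:
    """Full dispatch/completion trace plus worker topology."""

    trace: List[dict] = field(default_factory=list)
    states: Dict[str, str] = field(default_factory=dict)
    spawn_failures: List[str] = field(default_factory=list)
    topology: Dict[str, Optional[str]] = field(default_factory=dict)
    tiers: Dict[str, int] = field(default_factory=dict)
    mode: str = "serial"
    _seq: int = 0

    def record(self, event: str, instance: Optional[str] = None,
               worker: Optional[str] = None, **extra) -> None:
        self._seq += 1
        self.trace.append({"seq": self._seq, "event": event,
                           "instance": instance, "worker": worker, **extra})

    def max_tier(self) -> int:
        return max(self.tiers.values(), default=0)

    def dependency_violations(self, instances: Sequence[StepInstance]
                              ) -> List[str]:
        """Instances whose dispatch precedes a dependency's completion
        in the trace — empty for a safe run."""
        by_id = {i.id: i for i in instances}
        first_dispatch: Dict[str, int] = {}
        first_done: Dict[str, int] = {}
        for ev in self.trace:
            if ev["event"] == "dispatch":
                first_dispatch.setdefault(ev["instance"], ev["seq"])
            elif ev["event"] == "done":
                first_done.setdefault(ev["instance"], ev["seq"])
        bad = []
        for iid, seq in first_dispatch.items():
            inst = by_id.get(iid)
            if inst is None:
                continue
            for dep in inst.deps:
                if dep not in first_done or first_done[dep] >= seq:
                    bad.append(iid)
                    break
        return bad


# ---------------------------------------------------------------------------
# planning

def _toposort_steps(job: Job) -> List[Step]:
    indeg = {s.name: len(s.depends_on) for s in job.steps}
    dependents: Dict[str, list] = {s.name: [] for s in job.steps}
    for s in job.steps:
        for d in s.depends_on:
            dependents[d].append(s.name)
    ready = sorted(n for n, d in indeg.items() if d == 0)
    order = []
    by_name = {s.name: s for s in job.steps}
    while ready:
        n = ready.pop(0)
        order.append(by_name[n])
        for m in sorted(dependents[n]):
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
        ready.sort()
    if len(order) != len(job.steps):
        cycle = sorted(n for n, d in indeg.items() if d > 0)
        raise PlanningError(
            f"job {job.name}: cyclic step dependencies among {cycle}")
    return order


def plan(jobs: Sequence[Job], md5_list: Sequence[str], chunk_size: int
         ) -> List[StepInstance]:
    """Expand jobs over the deduplicated sequence set.

    Chunkable steps yield ``ceil(n / chunk_size)`` instances, each
    bound to one chunk (all chunks but the last have exactly
    *chunk_size* members); non-chunkable steps yield one instance.
    Instance dependencies follow step dependencies: chunk-aligned
    between chunkable steps, fan-in onto non-chunkable steps, fan-out
    from non-chunkable to chunkable.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    md5s = list(md5_list)
    chunks = [ChunkSpec(i, tuple(md5s[i * chunk_size:(i + 1) * chunk_size]))
              for i in range((len(md5s) + chunk_size - 1) // chunk_size)]
    instances: List[StepInstance] = []
    for job in jobs:
        order = _toposort_steps(job)
        made: Dict[str, List[StepInstance]] = {}
        for step in order:
            if step.chunkable:
                insts = [StepInstance(job_name=job.name, step=step,
                                      chunk=c, n_chunks=len(chunks))
                         for c in chunks]
            else:
                insts = [StepInstance(job_name=job.name, step=step,
                                      chunk=None, n_chunks=len(chunks))]
            for inst in insts:
                deps = []
                for dname in sorted(step.depends_on):
                    dep_insts = made[dname]
                    if step.chunkable and dep_insts and \
                            dep_insts[0].chunk is not None:
                        # chunk-aligned
                        deps.append(dep_insts[inst.chunk.chunk_index].id)
                    else:
                        deps.extend(d.id for d in dep_insts)
                inst.deps = tuple(deps)
            made[step.name] = insts
            instances.extend(insts)
    return instances


# ---------------------------------------------------------------------------
# step execution (shared by both modes)

def execute_step(context: dict, descriptor: dict, in_worker: bool = False
                 ) -> None:
    """Execute one step instance against the shared working directory.

    Honors the fault-injection hook (used to exercise worker-death
    recovery): when configured for this instance and the marker file is
    absent, the executing worker process exits abruptly mid-step.
    """
    from . import steps as step_funcs  # late import: keep engine generic

    fi = context.get("fault_injection")
    if in_worker and fi and fi.get("instance") == descriptor["id"]:
        marker = fi["marker"]
        if not os.path.exists(marker):
            with open(marker, "w") as fh:
                fh.write("died\n")
            # let in-flight queue messages flush so the abrupt death
            # cannot leave a shared queue lock held by a dead process
            time.sleep(0.5)
            os._exit(17)
    step_funcs.run(context, descriptor)


# ---------------------------------------------------------------------------
# serial mode

def _run_serial(instances: List[StepInstance], context: dict,
                policy: WorkerPolicy, report: ExecutionReport) -> None:
    by_id = {i.id: i for i in instances}
    done: set = set()
    remaining = sorted(instances, key=StepInstance.sort_key)
    while remaining:
        progressed = False
        for inst in list(remaining):
            if not all(d in done for d in inst.deps):
                continue
            inst.state = READY
            while True:
                inst.state = DISPATCHED
                inst.attempts += 1
                report.record("dispatch", inst.id, worker="master")
                try:
                    execute_step(context, inst.descriptor())
                except Exception:
                    diag = traceback.format_exc()
                    report.record("failed", inst.id, worker="master",
                                  error=diag)
                    if inst.attempts >= policy.retry_limit:
                        inst.state = FAILED
                        report.states.update(
                            {i.id: i.state for i in instances})
                        raise ExecutionError(
                            f"step instance {inst.id} failed after "
                            f"{inst.attempts} attempts", report,
                            instance_id=inst.id, diagnostics=diag)
                    report.record("retry", inst.id, worker="master")
                    continue
                inst.state = DONE
                report.record("done", inst.id, worker="master")
                done.add(inst.id)
                remaining.remove(inst)
                progressed = True
                break
        if remaining and not progressed:
            raise ExecutionError(
                f"no runnable instances among {sorted(i.id for i in remaining)}"
                " (unsatisfiable dependencies)", report)
    report.states.update({i.id: i.state for i in instances})


# ---------------------------------------------------------------------------
# multiprocess mode: worker side

def _worker_main(worker_id: str, tier: int, request_q, response_q,
                 control_recv, policy: WorkerPolicy, context: dict) -> None:
    children: list[tuple[str, mp.Process, object]] = []
    child_serial = 0
    last_work = time.monotonic()
    response_q.put(("worker_ready", worker_id, None))
    while True:
        # control messages from the parent
        while control_recv is not None and control_recv.poll(0):
            msg = control_recv.recv()
            if msg == "exit":
                for _, proc, conn in children:
                    try:
                        conn.send("exit")
                    except Exception:
                        pass
                return
            if isinstance(msg, tuple) and msg[0] == "spawn":
                count = msg[1]
                for _ in range(count):
                    child_serial += 1
                    cid = f"{worker_id}.{child_serial}"
                    if tier + 1 > policy.max_tiers:
                        response_q.put(("spawn_failed", cid,
                                        f"tier limit {policy.max_tiers}"))
                        continue
                    if len([c for c in children if c[1].is_alive()]) \
                            >= policy.max_direct_workers and children:
                        # delegate deeper
                        children[0][2].send(("spawn", 1))
                        continue
                    try:
                        parent_conn, child_conn = mp.Pipe()
                        proc = mp.Process(
                            target=_worker_main,
                            args=(cid, tier + 1, request_q, response_q,
                                  child_conn, policy, context),
                            daemon=False)
                        proc.start()
                    except Exception as exc:
                        response_q.put(("spawn_failed", cid, str(exc)))
                        continue
                    children.append((cid, proc, parent_conn))
                    response_q.put(("spawned", cid,
                                    {"parent": worker_id, "tier": tier + 1}))
        # reap dead children
        for entry in list(children):
            cid, proc, conn = entry
            if not proc.is_alive():
                proc.join(timeout=0)
                children.remove(entry)
                response_q.put(("worker_died", cid, None))
        try:
            item = request_q.get(timeout=0.1)
        except queue_mod.Empty:
            idle = time.monotonic() - last_work
            if idle > policy.worker_lifetime and not children:
                response_q.put(("worker_exit", worker_id, None))
                return
            continue
        if item is None:  # poison pill
            for _, proc, conn in children:
                try:
                    conn.send("exit")
                except Exception:
                    pass
            response_q.put(("worker_exit", worker_id, None))
            return
        last_work = time.monotonic()
        descriptor = item
        response_q.put(("started", descriptor["id"], worker_id))
        try:
            execute_step(context, descriptor, in_worker=True)
        except BaseException:
            response_q.put(("failed", descriptor["id"],
                            {"worker": worker_id,
                             "error": traceback.format_exc()}))
        else:
            response_q.put(("done", descriptor["id"], worker_id))
        last_work = time.monotonic()


# ---------------------------------------------------------------------------
# multiprocess mode: master side

class _Master:
    def __init__(self, instances, context, policy, report, max_workers,
                 spawn_hook):
        self.instances = instances
        self.by_id = {i.id: i for i in instances}
        self.context = context
        self.policy = policy
        self.report = report
        self.max_workers = max_workers
        self.spawn_hook = spawn_hook
        self.request_q = mp.Queue()
        self.response_q = mp.Queue()
        self.direct: list[tuple[str, mp.Process, object]] = []
        self.alive: set[str] = set()
        self.running_on: Dict[str, str] = {}  # instance -> worker
        self.enqueued: set[str] = set()
        self.done: set[str] = set()
        self.worker_serial = 0
        self.pending_delegations = 0
        self.descendant_counts: Dict[str, int] = {}

    # -- worker management ----------------------------------------------
    def total_known_alive(self) -> int:
        direct_ids = {wid for wid, p, _ in self.direct if p.is_alive()}
        return len(self.alive | direct_ids) + self.pending_delegations

    def spawn_one(self):
        if self.spawn_hook is not None:
            try:
                self.spawn_hook()
            except Exception as exc:
                self.report.spawn_failures.append(str(exc))
                self.report.record("spawn_failed", worker=None,
                                   error=str(exc))
                return
        direct_alive = [e for e in self.direct if e[1].is_alive()]
        if len(direct_alive) < self.policy.max_direct_workers:
            self.worker_serial += 1
            wid = f"w{self.worker_serial}"
            parent_conn, child_conn = mp.Pipe()
            try:
                proc = mp.Process(
                    target=_worker_main,
                    args=(wid, 1, self.request_q, self.response_q,
                          child_conn, self.policy, self.context),
                    daemon=False)
                proc.start()
            except Exception as exc:
                self.report.spawn_failures.append(str(exc))
                self.report.record("spawn_failed", worker=wid,
                                   error=str(exc))
                return
            self.direct.append((wid, proc, parent_conn))
            self.report.topology[wid] = None
            self.report.tiers[wid] = 1
            self.report.record("spawn", worker=wid, tier=1)
        elif direct_alive:
            # delegate to the direct worker with the fewest descendants
            target = min(direct_alive,
                         key=lambda e: self.descendant_counts.get(e[0], 0))
            try:
                target[2].send(("spawn", 1))
                self.pending_delegations += 1
                self.descendant_counts[target[0]] = \
                    self.descendant_counts.get(target[0], 0) + 1
                self.report.record("delegate_spawn", worker=target[0])
            except Exception as exc:
                self.report.spawn_failures.append(str(exc))

    def manage_workers(self, backlog: int):
        demand = min(self.max_workers, backlog)
        while self.total_known_alive() < demand:
            before = (len(self.direct), self.pending_delegations)
            self.spawn_one()
            if (len(self.direct), self.pending_delegations) == before:
                break  # spawning is failing; don't spin

    def reap_direct(self):
        for entry in list(self.direct):
            wid, proc, conn = entry
            if not proc.is_alive() and wid in self.alive:
                proc.join(timeout=0)
                self.on_worker_death(wid)

    def on_worker_death(self, wid: str):
        self.alive.discard(wid)
        self.report.record("worker_died", worker=wid)
        lost = [iid for iid, w in self.running_on.items() if w == wid]
        for iid in lost:
            del self.running_on[iid]
            inst = self.by_id[iid]
            if inst.state == DONE:
                continue
            if inst.attempts >= self.policy.retry_limit:
                raise ExecutionError(
                    f"step instance {iid} failed after {inst.attempts} "
                    f"attempts (worker {wid} died)", self.report,
                    instance_id=iid, diagnostics=f"worker {wid} died")
            self.requeue(inst)

    def requeue(self, inst: StepInstance):
        inst.state = READY
        self.enqueued.discard(inst.id)
        self.report.record("retry", inst.id)

    # -- dispatch --------------------------------------------------------
    def dispatch_ready(self):
        for inst in sorted(self.instances, key=StepInstance.sort_key):
            if inst.id in self.enqueued or inst.state in (DONE, DISPATCHED):
                continue
            if inst.state == FAILED:
                continue
            if all(d in self.done for d in inst.deps):
                inst.state = DISPATCHED
                self.enqueued.add(inst.id)
                self.report.record("dispatch", inst.id)
                self.request_q.put(inst.descriptor())

    # -- responses -------------------------------------------------------
    def handle(self, msg) -> bool:
        """Process one response message; returns True on progress."""
        kind, a, b = msg
        if kind == "worker_ready":
            self.alive.add(a)
            return True
        if kind == "spawned":
            self.alive.add(a)
            self.pending_delegations = max(0, self.pending_delegations - 1)
            self.report.topology[a] = b["parent"]
            self.report.tiers[a] = b["tier"]
            self.report.record("spawn", worker=a, tier=b["tier"],
                               parent=b["parent"])
            return True
        if kind == "spawn_failed":
            self.pending_delegations = max(0, self.pending_delegations - 1)
            self.report.spawn_failures.append(f"{a}: {b}")
            self.report.record("spawn_failed", worker=a, error=b)
            return True
        if kind == "worker_exit":
            self.alive.discard(a)
            self.report.record("worker_exit", worker=a)
            return True
        if kind == "worker_died":
            self.on_worker_death(a)
            return True
        if kind == "started":
            inst = self.by_id[a]
            if inst.state != DONE:
                inst.attempts += 1
                self.running_on[a] = b
                self.report.record("started", a, worker=b)
            return True
        if kind == "done":
            inst = self.by_id[a]
            self.running_on.pop(a, None)
            if inst.state != DONE:
                inst.state = DONE
                self.done.add(a)
                self.report.record("done", a, worker=b)
            return True
        if kind == "failed":
            inst = self.by_id[a]
            self.running_on.pop(a, None)
            if inst.state == DONE:
                return True
            self.report.record("failed", a, worker=b.get("worker"),
                               error=b.get("error"))
            if inst.attempts >= self.policy.retry_limit:
                inst.state = FAILED
                raise ExecutionError(
                    f"step instance {a} failed after {inst.attempts} "
                    "attempts", self.report, instance_id=a,
                    diagnostics=b.get("error"))
            self.requeue(inst)
            return True
        return False

    def run_inline_fallback(self):
        """With no live workers and spawning broken, the master executes
        work itself so the run still completes."""
        if not (self.enqueued - self.done):
            return
        try:
            item = self.request_q.get(timeout=0.2)
        except queue_mod.Empty:
            return
        if item is None:
            return
        inst = self.by_id[item["id"]]
        if inst.id in self.done:
            return
        inst.attempts += 1
        self.report.record("started", item["id"], worker="master")
        try:
            execute_step(self.context, item)
        except Exception:
            diag = traceback.format_exc()
            self.report.record("failed", item["id"], worker="master",
                               error=diag)
            if inst.attempts >= self.policy.retry_limit:
                inst.state = FAILED
                raise ExecutionError(
                    f"step instance {item['id']} failed", self.report,
                    instance_id=item["id"], diagnostics=diag)
            self.requeue(inst)
        else:
            inst.state = DONE
            self.done.add(item["id"])
            self.report.record("done", item["id"], worker="master")

    def shutdown(self):
        for _ in range(max(len(self.alive), len(self.direct)) + 2):
            try:
                self.request_q.put_nowait(None)
            except Exception:
                break
        for wid, proc, conn in self.direct:
            try:
                conn.send("exit")
            except Exception:
                pass
        deadline = time.monotonic() + 5
        for wid, proc, conn in self.direct:
            proc.join(timeout=max(0.1, deadline - time.monotonic()))
            if proc.is_alive():
                proc.terminate()
        self.request_q.cancel_join_thread()
        self.response_q.cancel_join_thread()

    def run(self):
        last_progress = time.monotonic()
        try:
            while len(self.done) < len(self.instances):
                self.dispatch_ready()
                backlog = len(self.enqueued - self.done)
                if backlog >= self.policy.backlog_threshold:
                    self.manage_workers(backlog)
                self.reap_direct()
                if not self.alive and not self.pending_delegations and \
                        not any(p.is_alive() for _, p, _ in self.direct):
                    self.run_inline_fallback()
                try:
                    msg = self.response_q.get(timeout=0.2)
                except queue_mod.Empty:
                    if time.monotonic() - last_progress > \
                            self.policy.stall_timeout:
                        for iid in sorted(self.enqueued - self.done):
                            inst = self.by_id[iid]
                            if inst.state == DISPATCHED:
                                self.requeue(inst)
                        last_progress = time.monotonic()
                    continue
                if self.handle(msg):
                    last_progress = time.monotonic()
        finally:
            self.shutdown()
        self.report.states.update({i.id: i.state for i in self.instances})


def run_master(instances: List[StepInstance], context: dict,
               policy: Optional[WorkerPolicy] = None, mode: str = "serial",
               max_workers: int = 4,
               spawn_hook: Optional[Callable[[], None]] = None
               ) -> ExecutionReport:
    """Execute a plan to completion and return the execution report.

    In ``serial`` mode instances run in-process in deterministic
    topological order (ties broken by job name, step name, chunk
    index).  In ``multiprocess`` mode up to *max_workers* worker
    processes are spawned under the tiered policy.  Raises
    :class:`ExecutionError` after retry exhaustion, carrying the
    failing instance and its captured diagnostics.
    """
    policy = policy or WorkerPolicy()
    report = ExecutionReport(mode=mode)
    # instance ids must be unique and deps resolvable
    ids = [i.id for i in instances]
    if len(ids) != len(set(ids)):
        raise PlanningError("duplicate step instance ids")
    idset = set(ids)
    for i in instances:
        missing = [d for d in i.deps if d not in idset]
        if missing:
            raise PlanningError(
                f"instance {i.id} depends on unknown instance(s) {missing}")
    if mode == "serial":
        _run_serial(instances, context, policy, report)
    elif mode == "multiprocess":
        _Master(instances, context, policy, report, max_workers,
                spawn_hook).run()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return report


# ---------------------------------------------------------------------------
# declarative job definitions

ANALYSIS_JOB_TEMPLATE = [
    {"name": "write_fasta", "kind": "write_fasta", "chunkable": True,
     "depends_on": []},
    {"name": "scan", "kind": "run_analyzer_scan", "chunkable": True,
     "depends_on": ["write_fasta"]},
    {"name": "postprocess", "kind": "run_postprocess", "chunkable": True,
     "depends_on": ["scan"]},
    {"name": "persist", "kind": "persist_matches", "chunkable": False,
     "depends_on": ["postprocess"]},
]


def job_from_spec(name: str, step_specs: Sequence[dict]) -> Job:
    steps = [Step(name=s["name"], kind=s["kind"],
                  depends_on=frozenset(s.get("depends_on", ())),
                  chunkable=bool(s.get("chunkable", True)))
             for s in step_specs]
    return Job(name=name, steps=steps)


def load_jobs_yaml(path: str) -> Dict[str, List[dict]]:
    """Load declarative job/step wiring from a YAML config file.

    Top-level keys are job (template) names; each maps to a list of
    step specs with ``name``, ``kind``, ``depends_on``, ``chunkable``.
    """
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of job names")
    return {name: spec["steps"] if isinstance(spec, dict) else spec
            for name, spec in data.items()}


def analysis_job(name: str, template: Optional[Sequence[dict]] = None) -> Job:
    return job_from_spec(name, template or ANALYSIS_JOB_TEMPLATE)
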