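"""Planning, dependency wiring, and master/worker execution."""

import json
import os

import pytest

from sigscan.engine import (ExecutionError, Job, PlanningError, Step,
                            WorkerPolicy, analysis_job, load_jobs_yaml,
                            plan, run_master)
from sigscan.fixtures import FixtureSpec, generate
from sigscan.formats import read_fasta
from sigscan.steps import load_persisted_matches


def chain_job(name="J"):
    return analysis_job(name)


def diamond_job(name="D"):
    """write → {scanB, scanC} → postprocess: branching then merging."""
    return Job(name=name, steps=[
        Step("write_fasta", "write_fasta", frozenset(), True),
        Step("scanB", "run_analyzer_scan", frozenset({"write_fasta"}), True),
        Step("scanC", "run_analyzer_scan", frozenset({"write_fasta"}), True),
        Step("merge", "run_postprocess", frozenset({"scanB", "scanC"}),
             True),
    ])


class TestPlan:
    def test_chunk_sizes(self):
        md5s = [f"m{i}" for i in range(10)]
        instances = plan([chain_job()], md5s, 4)
        scans = [i for i in instances if i.step.name == "scan"]
        assert [len(i.chunk.md5_list) for i in scans] == [4, 4, 2]

    def test_fan_in_onto_non_chunkable_step(self):
        md5s = [f"m{i}" for i in range(10)]
        instances = plan([chain_job()], md5s, 4)
        persist = [i for i in instances if i.step.name == "persist"]
        assert len(persist) == 1
        assert sorted(persist[0].deps) == [
            "J/postprocess#0", "J/postprocess#1", "J/postprocess#2"]

    def test_chunk_aligned_dependencies(self):
        instances = plan([chain_job()], [f"m{i}" for i in range(6)], 3)
        for inst in instances:
            if inst.step.name == "postprocess":
                assert inst.deps == (f"J/scan#{inst.chunk.chunk_index}",)

    def test_cycle_detected_and_named(self):
        job = Job(name="C", steps=[
            Step("a", "write_fasta", frozenset({"b"}), True),
            Step("b", "run_analyzer_scan", frozenset({"a"}), True),
        ])
        with pytest.raises(PlanningError) as exc:
            plan([job], ["m"], 1)
        assert "a" in str(exc.value) and "b" in str(exc.value)

    def test_unknown_dependency_rejected_at_definition(self):
        with pytest.raises(ValueError):
            Job(name="X", steps=[
                Step("a", "write_fasta", frozenset({"ghost"}), True)])

    def test_declarative_yaml_round_trip(self, tmp_path):
        path = tmp_path / "jobs.yaml"
        path.write_text(
            "myjob:\n  steps:\n"
            "    - {name: w, kind: write_fasta, chunkable: true,"
            " depends_on: []}\n"
            "    - {name: s, kind: run_analyzer_scan, chunkable: true,"
            " depends_on: [w]}\n")
        specs = load_jobs_yaml(str(path))
        job = Job(name="myjob", steps=[
            Step(s["name"], s["kind"], frozenset(s["depends_on"]),
                 s["chunkable"]) for s in specs["myjob"]])
        assert [s.name for s in job.steps] == ["w", "s"]


@pytest.fixture(scope="module")
def engine_fixture(tmp_path_factory):
    d = str(tmp_path_factory.mktemp("engine"))
    fasta, data_dir, _, gt = generate(
        FixtureSpec(seed=21, n_proteins=9, n_placements=5), d)
    prots = read_fasta(fasta)
    return {"dir": d, "proteins": prots, "data_dir": data_dir, "gt": gt}


def make_context(engine_fixture, tmp_path, name="ctx"):
    workdir = str(tmp_path / name)
    os.makedirs(workdir, exist_ok=True)
    with open(os.path.join(workdir, "proteins.json"), "w") as fh:
        json.dump({p.md5: p.residues for p in engine_fixture["proteins"]},
                  fh, sort_keys=True)
    libdir = os.path.join(engine_fixture["data_dir"], "libraries",
                          "TOYLIB-1.0")
    return {"workdir": workdir, "libraries": {"TOYLIB": libdir,
                                              "D": libdir, "J": libdir}}


class TestSerialExecution:
    def test_topological_order_and_completion(self, engine_fixture,
                                              tmp_path):
        ctx = make_context(engine_fixture, tmp_path)
        md5s = [p.md5 for p in engine_fixture["proteins"]]
        instances = plan([analysis_job("TOYLIB")], md5s, 4)
        report = run_master(instances, ctx, mode="serial")
        assert all(s == "done" for s in report.states.values())
        assert report.dependency_violations(instances) == []
        matches = load_persisted_matches(ctx["workdir"], "TOYLIB")
        planted = {(r["md5"], r["signature"], r["start"], r["stop"])
                   for r in engine_fixture["gt"].matches}
        got = {(m.protein_md5, m.signature_accession, loc.start, loc.stop)
               for m in matches if m.status == "filtered_in"
               for loc in m.locations}
        assert got == planted

    def test_diamond_trace_respects_branch_and_merge(self, engine_fixture,
                                                     tmp_path):
        ctx = make_context(engine_fixture, tmp_path, "diamond")
        md5s = [p.md5 for p in engine_fixture["proteins"]][:3]
        instances = plan([diamond_job("D")], md5s, 3)
        report = run_master(instances, ctx, mode="serial")
        order = [e["instance"] for e in report.trace
                 if e["event"] == "done"]
        assert order.index("D/write_fasta#0") < order.index("D/scanB#0")
        assert order.index("D/write_fasta#0") < order.index("D/scanC#0")
        assert order.index("D/merge#0") == len(order) - 1

    def test_serial_mode_is_deterministic(self, engine_fixture, tmp_path):
        md5s = [p.md5 for p in engine_fixture["proteins"]]
        outs = []
        for name in ("d1", "d2"):
            ctx = make_context(engine_fixture, tmp_path, name)
            run_master(plan([analysis_job("TOYLIB")], md5s, 4), ctx,
                       mode="serial")
            with open(os.path.join(ctx["workdir"], "TOYLIB",
                                   "matches.json"), "rb") as fh:
                outs.append(fh.read())
        assert outs[0] == outs[1]

    def test_reexecuting_done_instance_leaves_results_unchanged(
            self, engine_fixture, tmp_path):
        from sigscan.engine import execute_step
        ctx = make_context(engine_fixture, tmp_path, "idem")
        md5s = [p.md5 for p in engine_fixture["proteins"]]
        instances = plan([analysis_job("TOYLIB")], md5s, 4)
        run_master(instances, ctx, mode="serial")
        target = os.path.join(ctx["workdir"], "TOYLIB", "matches.json")
        with open(target, "rb") as fh:
            before = fh.read()
        persist = [i for i in instances if i.step.name == "persist"][0]
        execute_step(ctx, persist.descriptor())
        with open(target, "rb") as fh:
            assert fh.read() == before

    def test_retry_exhaustion_aborts_with_diagnostics(self, tmp_path):
        # scan without its chunk FASTA fails; retry limit then aborts
        job = Job(name="J", steps=[
            Step("scan", "run_analyzer_scan", frozenset(), True)])
        ctx = {"workdir": str(tmp_path), "libraries": {}}
        instances = plan([job], ["m1"], 1)
        with pytest.raises(ExecutionError) as exc:
            run_master(instances, ctx, mode="serial",
                       policy=WorkerPolicy(retry_limit=2))
        assert exc.value.instance_id == "J/scan#0"
        assert exc.value.diagnostics
        retries = [e for e in exc.value.report.trace
                   if e["event"] == "retry"]
        assert len(retries) == 1  # one re-attempt before aborting


class TestMultiprocessExecution:
    def test_equivalent_to_serial(self, engine_fixture, tmp_path):
        md5s = [p.md5 for p in engine_fixture["proteins"]]
        results = {}
        for mode in ("serial", "multiprocess"):
            ctx = make_context(engine_fixture, tmp_path, mode)
            report = run_master(plan([analysis_job("TOYLIB")], md5s, 3),
                                ctx, mode=mode,
                                policy=WorkerPolicy(worker_lifetime=2.0))
            with open(os.path.join(ctx["workdir"], "TOYLIB",
                                   "matches.json"), "rb") as fh:
                results[mode] = fh.read()
            assert all(s == "done" for s in report.states.values())
        assert results["serial"] == results["multiprocess"]

    def test_spawn_hook_failure_is_tolerated(self, engine_fixture,
                                             tmp_path):
        calls = {"n": 0}

        def flaky_spawn():
            calls["n"] += 1
            raise RuntimeError("no capacity on cluster")

        ctx = make_context(engine_fixture, tmp_path, "flaky")
        md5s = [p.md5 for p in engine_fixture["proteins"]]
        instances = plan([analysis_job("TOYLIB")], md5s, 4)
        report = run_master(instances, ctx, mode="multiprocess",
                            policy=WorkerPolicy(worker_lifetime=2.0),
                            spawn_hook=flaky_spawn)
        assert report.spawn_failures
        assert all(s == "done" for s in report.states.values())


class TestWorkerPolicy:
    def test_positive_integer_validation(self):
        with pytest.raises(ValueError):
            WorkerPolicy(max_direct_workers=0)
        with pytest.raises(ValueError):
            WorkerPolicy(retry_limit=0)
        with pytest.raises(ValueError):
            WorkerPolicy(worker_lifetime=0)
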