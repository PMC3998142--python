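"""Concrete step functions executed by the job engine.

A step instance's descriptor plus the shared working directory is all a
worker needs: the working directory holds the deduplicated protein set
(``proteins.json``: md5 → residues) and per-job subdirectories for
chunk FASTA files and match artifacts.  Every output is written to an
instance-scoped temporary path and atomically renamed, so re-executing
a completed instance (at-least-once delivery) leaves results unchanged.

Layout under ``workdir``::

    proteins.json
    <job>/chunk_<k>.fasta
    <job>/raw_<k>.json        scanner output (status raw)
    <job>/filtered_<k>.json   post-processed (statuses set)
    <job>/matches.json        merged, canonically sorted
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Dict, List

from .library import load_library
from .model import (Match, ProteinSequence, canonicalize_and_checksum,
                    match_from_dict, match_to_dict)


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(path)
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=os.path.basename(path) + ".tmp.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _load_proteins(context: dict) -> Dict[str, str]:
    with open(os.path.join(context["workdir"], "proteins.json")) as fh:
        return json.load(fh)


def _library_for(context: dict, job: str):
    return load_library(context["libraries"][job])


def _jobdir(context: dict, job: str) -> str:
    return os.path.join(context["workdir"], job)


def step_write_fasta(context: dict, d: dict) -> None:
    proteins = _load_proteins(context)
    lines = []
    for md5 in d["md5s"]:
        lines.append(f">{md5}")
        residues = proteins[md5]
        lines.extend(residues[i:i + 60] for i in range(0, len(residues), 60))
    path = os.path.join(_jobdir(context, d["job"]),
                        f"chunk_{d['chunk_index']}.fasta")
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def _read_chunk_proteins(context: dict, d: dict) -> List[ProteinSequence]:
    # chunk FASTA ids are checksums; re-canonicalizing reproduces them
    path = os.path.join(_jobdir(context, d["job"]),
                        f"chunk_{d['chunk_index']}.fasta")
    prots = []
    with open(path) as fh:
        rid, buf = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    prots.append(canonicalize_and_checksum(rid, "".join(buf)))
                rid, buf = line[1:].split()[0], []
            elif line:
                buf.append(line)
        if rid is not None:
            prots.append(canonicalize_and_checksum(rid, "".join(buf)))
    return prots


def _dump_matches(matches) -> str:
    return json.dumps([match_to_dict(m) for m in matches], sort_keys=True,
                      indent=0)


def step_run_analyzer_scan(context: dict, d: dict) -> None:
    release = _library_for(context, d["job"])
    prots = _read_chunk_proteins(context, d)
    raw = release.analyzer.scan(prots, release.signatures)
    raw.sort(key=Match.sort_key)
    path = os.path.join(_jobdir(context, d["job"]),
                        f"raw_{d['chunk_index']}.json")
    _atomic_write(path, _dump_matches(raw))


def step_run_postprocess(context: dict, d: dict) -> None:
    release = _library_for(context, d["job"])
    jobdir = _jobdir(context, d["job"])
    with open(os.path.join(jobdir, f"raw_{d['chunk_index']}.json")) as fh:
        raw = [match_from_dict(x) for x in json.load(fh)]
    processed = release.analyzer.postprocess(raw, release.signature_index())
    processed.sort(key=Match.sort_key)
    path = os.path.join(jobdir, f"filtered_{d['chunk_index']}.json")
    _atomic_write(path, _dump_matches(processed))


def step_persist_matches(context: dict, d: dict) -> None:
    jobdir = _jobdir(context, d["job"])
    merged: List[Match] = []
    for k in range(d["n_chunks"]):
        with open(os.path.join(jobdir, f"filtered_{k}.json")) as fh:
            merged.extend(match_from_dict(x) for x in json.load(fh))
    merged.sort(key=Match.sort_key)
    _atomic_write(os.path.join(jobdir, "matches.json"),
                  _dump_matches(merged))


_REGISTRY = {
    "write_fasta": step_write_fasta,
    "run_analyzer_scan": step_run_analyzer_scan,
    "run_postprocess": step_run_postprocess,
    "persist_matches": step_persist_matches,
}


def run(context: dict, descriptor: dict) -> None:
    try:
        fn = _REGISTRY[descriptor["kind"]]
    except KeyError:
        raise ValueError(f"unknown step kind {descriptor['kind']!r}")
    fn(context, descriptor)


def load_persisted_matches(workdir: str, job: str) -> List[Match]:
    with open(os.path.join(workdir, job, "matches.json")) as fh:
        return [match_from_dict(x) for x in json.load(fh)]
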