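"""End-to-end orchestration: FASTA in, annotated results out.

The pipeline reads protein or nucleotide input (translating ORFs for
the latter), deduplicates by checksum, short-circuits already-known
sequences through the match lookup store, plans and executes the
analysis jobs through the job engine, annotates filtered matches with
entry/GO/pathway information, and writes the requested output formats
from one canonical result document.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import steps
from .config import RunConfig
from .engine import (ExecutionReport, WorkerPolicy, analysis_job, plan,
                     run_master)
from .formats import (NucleotideRecord, OrfRef, ProteinResult, ProteinXref,
                      ResultDocument, make_document, read_fasta, write_gff3,
                      write_json, write_tsv, write_xml)
from .integration import IntegrationBundle, annotate, load_bundle
from .library import LibraryRelease, load_libraries
from .lookup import MatchStore, partition, query_service
from .model import (FILTERED_IN, Match, ProteinSequence, deduplicate)
from .orfs import find_orfs

logger = logging.getLogger(__name__)

_WRITERS = {"tsv": write_tsv, "xml": write_xml, "gff3": write_gff3,
            "json": write_json}


class UnknownAnalysisError(ValueError):
    def __init__(self, requested, available):
        super().__init__(
            f"unknown analysis {sorted(requested)}; available analyses: "
            f"{sorted(available)}")
        self.requested = requested
        self.available = available


@dataclass
class PipelineResult:
    document: ResultDocument
    outputs: Dict[str, str]
    report: Optional[ExecutionReport]
    lookup_hits: int = 0
    lookup_misses: int = 0


def _select_releases(config: RunConfig) -> Dict[str, LibraryRelease]:
    releases = load_libraries(config.data_dir)
    if not releases:
        raise ValueError(f"no signature libraries under {config.data_dir}")
    if config.analyses is None:
        return dict(sorted(releases.items()))
    unknown = set(config.analyses) - set(releases)
    if unknown:
        raise UnknownAnalysisError(unknown, set(releases))
    return {name: releases[name] for name in sorted(config.analyses)}


def _lookup_partition(proteins, config: RunConfig, versions, analyses):
    if config.disable_precalc or not config.lookup:
        return {}, list(proteins), None
    if config.lookup.startswith("http://") or \
            config.lookup.startswith("https://"):
        try:
            stamped, records = query_service(
                config.lookup, [p.md5 for p in proteins])
        except Exception as exc:
            logger.warning("lookup service %s unreachable (%s); analyzing "
                           "all sequences", config.lookup, exc)
            return {}, list(proteins), None
        if stamped != versions:
            logger.warning("lookup service version stamp mismatch; "
                           "ignoring precalculated matches")
            return {}, list(proteins), None
        hits, misses = {}, []
        for p in proteins:
            rec = records.get(p.md5)
            if rec is not None and all(a in rec for a in analyses):
                hits[p.md5] = {a: rec[a] for a in analyses}
            else:
                misses.append(p)
        return hits, misses, None
    if not os.path.exists(config.lookup):
        logger.warning("lookup store %s not found; analyzing all sequences",
                       config.lookup)
        return {}, list(proteins), None
    try:
        store = MatchStore(config.lookup)
    except Exception as exc:
        logger.warning("lookup store %s unusable (%s)", config.lookup, exc)
        return {}, list(proteins), None
    hits, misses = partition(proteins, store, versions, analyses)
    return hits, misses, store


def run_pipeline(config: RunConfig) -> PipelineResult:
    if not config.input:
        raise ValueError("no input file configured")
    if not config.data_dir:
        raise ValueError("no data directory configured")
    releases = _select_releases(config)
    analyses = list(releases)
    versions = {name: rel.version for name, rel in releases.items()}
    date = config.date or datetime.date.today().isoformat()

    # 1. input sequences (translating ORFs for nucleotide input)
    nucleotides: List[NucleotideRecord] = []
    orf_refs: Dict[str, OrfRef] = {}
    if config.seq_type == "n":
        nts = read_fasta(config.input, kind="nucleotide")
        proteins = []
        for nt in nts:
            nucleotides.append(NucleotideRecord(
                id=nt.id, residues=nt.residues, length=nt.length))
            for orf in find_orfs(nt, config.min_orf_length):
                proteins.append(orf.protein)
                orf_refs[orf.protein.id] = OrfRef(
                    parent_id=orf.parent_id, strand=orf.strand,
                    nt_start=orf.nt_start, nt_end=orf.nt_end)
    else:
        proteins = read_fasta(config.input, kind="protein")

    unique, alias_map = deduplicate(proteins)

    # 2. lookup partition
    hits, misses, store = _lookup_partition(unique, config, versions,
                                            analyses)

    # 3. plan and execute analysis jobs for the misses
    report = None
    computed: Dict[str, Dict[str, List[Match]]] = {}
    if misses and analyses:
        workdir = config.workdir or (
            (config.output_base or "sigscan_run") + ".work")
        os.makedirs(workdir, exist_ok=True)
        with open(os.path.join(workdir, "proteins.json"), "w") as fh:
            json.dump({p.md5: p.residues for p in misses}, fh,
                      sort_keys=True)
        lib_dirs = {}
        root = os.path.join(config.data_dir, "libraries")
        for entry in sorted(os.listdir(root)):
            sub = os.path.join(root, entry)
            if os.path.isdir(sub):
                from .library import load_library
                rel = load_library(sub)
                if rel.name in releases:
                    lib_dirs[rel.name] = sub
        context = {"workdir": workdir, "libraries": lib_dirs}
        if config.fault_injection:
            context["fault_injection"] = config.fault_injection
        jobs = [analysis_job(name) for name in analyses]
        md5s = [p.md5 for p in misses]
        instances = plan(jobs, md5s, config.chunk_size)
        report = run_master(instances, context,
                            policy=config.worker_policy(),
                            mode=config.mode,
                            max_workers=config.max_workers)
        for name in analyses:
            for m in steps.load_persisted_matches(workdir, name):
                computed.setdefault(m.protein_md5, {}).setdefault(
                    name, []).append(m)

    # 4. merge lookup hits and computed matches; annotate filtered_in
    bundle_dir = os.path.join(config.data_dir, "integration")
    bundle = load_bundle(bundle_dir) if os.path.isdir(bundle_dir) else \
        IntegrationBundle(entries=[], signature_to_entry={},
                          protein_pathway_annotations={})
    analysis_names = {}
    signature_names = {}
    for name, rel in releases.items():
        for sig in rel.signatures:
            analysis_names[sig.accession] = name
            signature_names[sig.accession] = sig.name

    prot_results = []
    for prot in unique:
        per_analysis = hits.get(prot.md5, {})
        for name, ms in computed.get(prot.md5, {}).items():
            per_analysis = dict(per_analysis)
            per_analysis[name] = ms
        filtered = [m for ms in per_analysis.values() for m in ms
                    if m.status == FILTERED_IN]
        annotated = annotate(filtered, bundle, analysis_names,
                             signature_names)
        if config.seq_type == "n":
            xrefs = tuple(ProteinXref(id=pid, orf=orf_refs[pid])
                          for pid in alias_map[prot.md5])
        else:
            xrefs = tuple(ProteinXref(id=pid)
                          for pid in alias_map[prot.md5])
        prot_results.append(ProteinResult(
            md5=prot.md5, length=prot.length, residues=prot.residues,
            xrefs=xrefs, matches=tuple(annotated)))

    doc = make_document(date=date,
                        analyses=sorted(versions.items()),
                        proteins=prot_results,
                        nucleotides=nucleotides)

    # 5. write requested formats
    outputs = {}
    if config.output_base:
        os.makedirs(os.path.dirname(os.path.abspath(config.output_base)),
                    exist_ok=True)
        for fmt in config.formats:
            fmt = fmt.lower()
            path = f"{config.output_base}.{fmt}"
            _WRITERS[fmt](doc, path)
            outputs[fmt] = path
    if store is not None:
        store.close()
    return PipelineResult(document=doc, outputs=outputs, report=report,
                          lookup_hits=len(hits), lookup_misses=len(misses))
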