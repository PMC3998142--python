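"""Signature library release bundles: a plain-text on-disk layout.

A release lives in one directory::

    <dir>/
      library.yaml      # name, version, modality (scan_filter | single_pass)
      signatures.tsv    # accession  name  model_kind  clan ('-' = none)
      patterns.txt      # accession <TAB> pattern string
      profiles.txt      # blocks: '>accession threshold=T L=n' + n rows of
                        # 20 floats ordered A C D E F G H I K L M N P Q R S T V W Y

The fixture generator emits exactly this layout; real signature
collections could be converted into it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import yaml

from .analyzers import (MODALITIES, AnalyzerContract, PatternModel,
                        ProfileModel, parse_pattern)
from .model import Signature


@dataclass
class LibraryRelease:
    name: str
    version: str
    modality: str
    signatures: List[Signature]

    @property
    def analyzer(self) -> AnalyzerContract:
        return MODALITIES[self.modality](self.name)

    def signature_index(self) -> Dict[str, Signature]:
        return {s.accession: s for s in self.signatures}


def load_library(dirpath: str) -> LibraryRelease:
    meta_path = os.path.join(dirpath, "library.yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("name", "version", "modality"):
        if key not in meta:
            raise ValueError(f"{meta_path}: missing key {key!r}")
    if meta["modality"] not in MODALITIES:
        raise ValueError(f"{meta_path}: unknown modality {meta['modality']!r}")

    patterns: Dict[str, PatternModel] = {}
    ppath = os.path.join(dirpath, "patterns.txt")
    if os.path.exists(ppath):
        with open(ppath) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                acc, pat = line.split("\t")
                patterns[acc] = parse_pattern(pat)

    profiles: Dict[str, ProfileModel] = {}
    prpath = os.path.join(dirpath, "profiles.txt")
    if os.path.exists(prpath):
        profiles = _read_profiles(prpath)

    signatures = []
    with open(os.path.join(dirpath, "signatures.tsv")) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, name, kind, clan = line.split("\t")
            clan_val = None if clan == "-" else clan
            if kind == "pattern":
                payload = patterns[acc]
            elif kind == "profile":
                payload = profiles[acc]
            else:
                raise ValueError(f"unknown model kind {kind!r} for {acc}")
            signatures.append(Signature(
                accession=acc, name=name, library=str(meta["name"]),
                library_version=str(meta["version"]), model_kind=kind,
                model_payload=payload, clan=clan_val))
    accs = [s.accession for s in signatures]
    if len(accs) != len(set(accs)):
        raise ValueError(f"duplicate signature accession in {dirpath}")
    return LibraryRelease(name=str(meta["name"]), version=str(meta["version"]),
                          modality=meta["modality"], signatures=signatures)


def _read_profiles(path: str) -> Dict[str, ProfileModel]:
    profiles: Dict[str, ProfileModel] = {}
    acc = None
    threshold = 0.0
    rows: list[list[float]] = []
    expect = 0

    def flush():
        if acc is None:
            return
        if len(rows) != expect:
            raise ValueError(f"{path}: profile {acc} expected {expect} rows, "
                             f"got {len(rows)}")
        profiles[acc] = ProfileModel(matrix=np.array(rows), threshold=threshold)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                acc = fields[0]
                kv = dict(f.split("=", 1) for f in fields[1:])
                threshold = float(kv["threshold"])
                expect = int(kv["L"])
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return profiles


def write_library(release: LibraryRelease, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "library.yaml"), "w") as fh:
        yaml.safe_dump({"name": release.name, "version": release.version,
                        "modality": release.modality}, fh,
                       default_flow_style=False, sort_keys=True)
    pats, profs = [], []
    with open(os.path.join(dirpath, "signatures.tsv"), "w") as fh:
        for s in sorted(release.signatures, key=lambda s: s.accession):
            fh.write(f"{s.accession}\t{s.name}\t{s.model_kind}\t"
                     f"{s.clan or '-'}\n")
            (pats if s.model_kind == "pattern" else profs).append(s)
    if pats:
        with open(os.path.join(dirpath, "patterns.txt"), "w") as fh:
            for s in pats:
                fh.write(f"{s.accession}\t{s.model_payload.pattern}\n")
    if profs:
        with open(os.path.join(dirpath, "profiles.txt"), "w") as fh:
            for s in profs:
                m: ProfileModel = s.model_payload
                fh.write(f">{s.accession} threshold={m.threshold:g} "
                         f"L={m.length}\n")
                for row in m.matrix:
                    fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def load_libraries(data_dir: str) -> Dict[str, LibraryRelease]:
    """Load every library release under ``<data_dir>/libraries``."""
    root = os.path.join(data_dir, "libraries")
    releases: Dict[str, LibraryRelease] = {}
    if not os.path.isdir(root):
        return releases
    for entry in sorted(os.listdir(root)):
        sub = os.path.join(root, entry)
        if os.path.isdir(sub) and os.path.exists(
                os.path.join(sub, "library.yaml")):
            rel = load_library(sub)
            releases[rel.name] = rel
    return releases
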