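"""Run configuration.

All defaults live in one bundled config file
(``sigscan/data/default_config.yaml``); a user config file overrides the
defaults and command-line flags override both.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields
from typing import List, Optional

import yaml

from .engine import WorkerPolicy

ALL_FORMATS = ["tsv", "xml", "gff3", "json"]


@dataclass
class RunConfig:
    input: Optional[str] = None
    seq_type: str = "p"                  # p = protein, n = nucleotide
    formats: List[str] = field(default_factory=lambda: list(ALL_FORMATS))
    output_base: Optional[str] = None
    analyses: Optional[List[str]] = None  # None = all configured
    data_dir: Optional[str] = None
    chunk_size: int = 1000
    mode: str = "serial"
    max_workers: int = 4
    max_direct_workers: int = 4
    max_tiers: int = 3
    worker_lifetime: float = 5.0
    retry_limit: int = 2
    disable_precalc: bool = False
    lookup: Optional[str] = None          # store path or http URL
    min_orf_length: int = 50
    date: Optional[str] = None            # override for reproducible output
    workdir: Optional[str] = None
    fault_injection: Optional[dict] = None  # engine chaos hook (testing)

    def worker_policy(self) -> WorkerPolicy:
        return WorkerPolicy(max_direct_workers=self.max_direct_workers,
                            max_tiers=self.max_tiers,
                            worker_lifetime=self.worker_lifetime,
                            retry_limit=self.retry_limit)


def builtin_defaults() -> dict:
    ref = importlib.resources.files("sigscan").joinpath(
        "data/default_config.yaml")
    return yaml.safe_load(ref.read_text())


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Built-in defaults ← optional config file ← keyword overrides."""
    values = builtin_defaults()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - {f.name for f in fields(RunConfig)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(user)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(**values)
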