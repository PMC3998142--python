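"""Checksum-keyed store of precomputed matches.

Before any analysis is launched, each submitted protein's MD5 checksum
is looked up in the store; proteins already characterized get their
stored matches back verbatim and only the remainder is analyzed.  The
lookup is an optimization, never a correctness dependency: an
unreachable or corrupt store simply turns every protein into a miss
(with a warning).

The store is an embedded single-file SQLite database stamped with the
exact signature-library release versions it was computed against; a
stamp mismatch invalidates the whole store for that run.  A protein
counts as a hit only when the store covers *all* requested analyses;
hits are filtered down to the requested analyses.

A minimal HTTP front-end (batch md5 queries returning JSON) preserves
the web-service deployment shape; see :class:`LookupServer`.
"""

from __future__ import annotations

import json
import logging
import sqlite3
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
from urllib import request as urlrequest

from .model import Match, ProteinSequence, match_from_dict, match_to_dict

logger = logging.getLogger(__name__)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS records (
    md5 TEXT PRIMARY KEY,
    payload TEXT NOT NULL
);
"""


class MatchStore:
    """Embedded key-value store: protein md5 → per-analysis match lists.

    The version stamp is a mapping {library name: release version}; a
    record's payload is ``{"analyses": {name: [match dicts]}}`` so the
    store knows exactly which analyses each record covers.
    """

    def __init__(self, path: str):
        self.path = path
        # the HTTP front-end serves from handler threads
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._lock = threading.Lock()
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self):
        self._conn.close()

    # -- version stamp ---------------------------------------------------
    def set_versions(self, versions: Mapping[str, str]) -> None:
        payload = json.dumps(dict(sorted(versions.items())))
        with self._lock:
            self._conn.execute(
                "INSERT OR REPLACE INTO meta (key, value) "
                "VALUES ('versions', ?)", (payload,))
            self._conn.commit()

    def versions(self) -> Optional[Dict[str, str]]:
        with self._lock:
            row = self._conn.execute(
                "SELECT value FROM meta WHERE key='versions'").fetchone()
        return json.loads(row[0]) if row else None

    # -- records ---------------------------------------------------------
    def put(self, md5: str, matches_by_analysis: Mapping[str, Sequence[Match]]
            ) -> None:
        payload = json.dumps(
            {"analyses": {name: [match_to_dict(m) for m in ms]
                          for name, ms in sorted(matches_by_analysis.items())}},
            sort_keys=True)
        with self._lock:
            self._conn.execute(
                "INSERT OR REPLACE INTO records (md5, payload) "
                "VALUES (?, ?)", (md5, payload))
            self._conn.commit()

    def get(self, md5: str) -> Optional[Dict[str, List[Match]]]:
        with self._lock:
            row = self._conn.execute(
                "SELECT payload FROM records WHERE md5=?",
                (md5,)).fetchone()
        if row is None:
            return None
        data = json.loads(row[0])
        return {name: [match_from_dict(d) for d in ds]
                for name, ds in data["analyses"].items()}

    def batch(self, md5s: Iterable[str]) -> Dict[str, Dict[str, List[Match]]]:
        out = {}
        for md5 in md5s:
            rec = self.get(md5)
            if rec is not None:
                out[md5] = rec
        return out

    def __len__(self) -> int:
        with self._lock:
            return self._conn.execute(
                "SELECT COUNT(*) FROM records").fetchone()[0]


def partition(proteins: Sequence[ProteinSequence],
              store: Optional[MatchStore],
              expected_versions: Mapping[str, str],
              analyses: Sequence[str]
              ) -> Tuple[Dict[str, Dict[str, List[Match]]],
                         List[ProteinSequence]]:
    """Split *proteins* into lookup hits and misses.

    Returns ``(hits, misses)`` where ``hits`` maps md5 → {analysis:
    matches} for proteins fully covered by the store, and ``misses``
    lists the proteins that must be analyzed.  The union covers all
    inputs with no overlap.  A missing store, version-stamp mismatch or
    any store error yields all misses (warned, never fatal).
    """
    if store is None:
        return {}, list(proteins)
    try:
        stamped = store.versions()
        if stamped != dict(expected_versions):
            logger.warning(
                "lookup store version stamp %s does not match configured "
                "analyses %s; ignoring store", stamped,
                dict(expected_versions))
            return {}, list(proteins)
        hits: Dict[str, Dict[str, List[Match]]] = {}
        misses: List[ProteinSequence] = []
        wanted = list(analyses)
        for prot in proteins:
            rec = store.get(prot.md5)
            if rec is not None and all(a in rec for a in wanted):
                hits[prot.md5] = {a: rec[a] for a in wanted}
            else:
                misses.append(prot)
        return hits, misses
    except Exception as exc:  # corrupt store: lookup is only an optimization
        logger.warning("lookup store %s unusable (%s); analyzing all "
                       "sequences", getattr(store, "path", "?"), exc)
        return {}, list(proteins)


def build_store(path: str, versions: Mapping[str, str],
                matches_by_md5: Mapping[str, Mapping[str, Sequence[Match]]]
                ) -> MatchStore:
    store = MatchStore(path)
    store.set_versions(versions)
    for md5, by_analysis in matches_by_md5.items():
        store.put(md5, by_analysis)
    return store


def load_store(xml_paths: Sequence[str], store_path: str) -> MatchStore:
    """Build a store from prior-run result XML files.

    One record per distinct md5; re-loading the same file is
    idempotent.  Parse/schema violations propagate (naming the element
    and line) and leave no partial record behind for that file.
    """
    from .formats import read_xml  # local import to avoid a cycle

    docs = [read_xml(p) for p in xml_paths]  # validate everything first
    store = MatchStore(store_path)
    versions: Dict[str, str] = {}
    for doc in docs:
        versions.update(dict(doc.analyses))
    store.set_versions(versions)
    analysis_names = sorted(versions)
    for doc in docs:
        for prot in doc.proteins:
            by_analysis: Dict[str, List[Match]] = {a: [] for a in analysis_names}
            for am in prot.matches:
                by_analysis.setdefault(am.analysis, []).append(am.match)
            store.put(prot.md5, by_analysis)
    return store


# ---------------------------------------------------------------------------
# minimal HTTP front-end (batch md5 query)

class _Handler(BaseHTTPRequestHandler):
    store: MatchStore = None  # type: ignore[assignment]

    def do_POST(self):
        if self.path != "/matches":
            self.send_error(404)
            return
        length = int(self.headers.get("Content-Length", 0))
        try:
            md5s = json.loads(self.rfile.read(length))
            assert isinstance(md5s, list)
        except Exception:
            self.send_error(400, "expected a JSON list of md5 strings")
            return
        result = {
            md5: {name: [match_to_dict(m) for m in ms]
                  for name, ms in rec.items()}
            for md5, rec in self.server.store.batch(md5s).items()}
        body = json.dumps({"versions": self.server.store.versions(),
                           "records": result}).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def log_message(self, *args):  # quiet
        pass


class LookupServer:
    """Serve a :class:`MatchStore` over HTTP on localhost.

    POST /matches with a JSON list of md5 strings returns
    ``{"versions": {...}, "records": {md5: {analysis: [match...]}}}``.
    """

    def __init__(self, store: MatchStore, port: int = 0):
        self._httpd = ThreadingHTTPServer(("127.0.0.1", port), _Handler)
        self._httpd.store = store
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        daemon=True)

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address
        return f"http://{host}:{port}"

    def start(self):
        self._thread.start()
        return self

    def stop(self):
        self._httpd.shutdown()
        self._httpd.server_close()


def query_service(url: str, md5s: Sequence[str]
                  ) -> Tuple[Optional[Dict[str, str]],
                             Dict[str, Dict[str, List[Match]]]]:
    """Batch-query a lookup service; returns (versions, records)."""
    req = urlrequest.Request(
        url.rstrip("/") + "/matches",
        data=json.dumps(list(md5s)).encode(),
        headers={"Content-Type": "application/json"})
    with urlrequest.urlopen(req, timeout=30) as resp:
        data = json.loads(resp.read())
    records = {
        md5: {name: [match_from_dict(d) for d in ds]
              for name, ds in rec.items()}
        for md5, rec in data["records"].items()}
    return data.get("versions"), records
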