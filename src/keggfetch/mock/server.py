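"""A local HTTP service speaking the KEGG REST grammar.

:class:`MockKEGGServer` serves a :class:`~keggfetch.mock.dataset.MockDataset`
over ``http://127.0.0.1:<port>`` with the same path grammar as the real
KEGG API (info/list/get/find/conv/link/ddi), including the server-side
quirks the real service exhibits:

* at most 10 entries per ``get`` request (more is a non-200 status);
* for single-only entry fields — and optionally for every grouped
  request — only the first requested entry is returned, silently, with
  status 200;
* over-long request lines are rejected with a non-200 status;
* optional blacklisting, either deterministic (requests arriving within
  a cooldown of the previous request get 403 until the client backs
  off) or probabilistic with a seeded RNG;
* optional fixed response delay (for timeout tests) and a scripted
  per-request outcome sequence (for retry tests).

Everything is deterministic given the dataset seed and the
:class:`QuirkConfig` seeds, so tests can use the dataset as a byte-exact
oracle for what a pull should have saved.
"""
from __future__ import annotations

import random
import threading
import time
import urllib.parse
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import List, Optional, Tuple, Union

from ..urls import ENTRY_FIELDS
from .dataset import MockDataset

#: Fields for which the server silently returns only the first entry.
DEFAULT_SINGLE_ONLY_FIELDS = frozenset({"image", "conf", "kgml", "json"})


@dataclass
class QuirkConfig:
    """Reconfigurable server-side behaviors.

    ``script`` is a sequence of per-request outcomes consumed in
    arrival order: an ``int`` forces that HTTP status (200 proceeds
    normally), the string ``"timeout"`` stalls the response for
    ``script_timeout_delay`` seconds.
    """

    max_entries_per_get: int = 10
    single_only_fields: frozenset = DEFAULT_SINGLE_ONLY_FIELDS
    first_entry_only: bool = False
    blacklist_cooldown: Optional[float] = None
    blacklist_rate: float = 0.0
    blacklist_seed: int = 0
    response_delay: float = 0.0
    script_timeout_delay: float = 1.0
    url_length_reject: int = 4096
    script: List[Union[int, str]] = field(default_factory=list)


class MockKEGGServer:
    """Threaded local KEGG endpoint over a mock dataset.

    Use as a context manager, or call :meth:`start`/:meth:`stop`.
    ``requests`` records ``(path, monotonic arrival time)`` for every
    request, so tests can count attempts and measure inter-request gaps.
    """

    def __init__(self, dataset: MockDataset,
                 quirks: Optional[QuirkConfig] = None, port: int = 0) -> None:
        self.dataset = dataset
        self.quirks = quirks if quirks is not None else QuirkConfig()
        self.requests: List[Tuple[str, float]] = []
        self._state_lock = threading.Lock()
        self._last_request_time: Optional[float] = None
        self._rng = random.Random(self.quirks.blacklist_seed)
        self._script = list(self.quirks.script)
        self._httpd = ThreadingHTTPServer(("127.0.0.1", port), _Handler)
        self._httpd.daemon_threads = True
        self._httpd.mock = self  # type: ignore[attr-defined]
        self._thread: Optional[threading.Thread] = None

    @property
    def base_url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "MockKEGGServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "MockKEGGServer":
        return self.start()

    def __exit__(self, *exc_info) -> None:
        self.stop()

    # -- request bookkeeping ----------------------------------------------

    def reset(self, quirks: Optional[QuirkConfig] = None) -> None:
        """Clear the request log and cooldown state; optionally swap quirks."""
        with self._state_lock:
            self.requests.clear()
            self._last_request_time = None
            if quirks is not None:
                self.quirks = quirks
                self._rng = random.Random(quirks.blacklist_seed)
                self._script = list(quirks.script)

    def request_paths(self, prefix: str = "") -> List[str]:
        with self._state_lock:
            return [path for path, _ in self.requests if path.startswith(prefix)]

    # -- request handling --------------------------------------------------

    def handle(self, path: str) -> Tuple[int, str, bytes]:
        quirks = self.quirks
        with self._state_lock:
            now = time.monotonic()
            self.requests.append((path, now))
            previous = self._last_request_time
            self._last_request_time = now
            scripted = self._script.pop(0) if self._script else None
            blacklisted = False
            if quirks.blacklist_cooldown is not None and previous is not None \
                    and (now - previous) < quirks.blacklist_cooldown:
                blacklisted = True
            if quirks.blacklist_rate and self._rng.random() < quirks.blacklist_rate:
                blacklisted = True
        if quirks.response_delay:
            time.sleep(quirks.response_delay)
        if scripted == "timeout":
            time.sleep(quirks.script_timeout_delay)
            return 200, "text/plain", b""
        if isinstance(scripted, int) and scripted != 200:
            return scripted, "text/plain", b"scripted error\n"
        request_line = f"GET {path} HTTP/1.1\r\n"
        if len(request_line) > quirks.url_length_reject:
            return 414, "text/plain", b"request line too long\n"
        if blacklisted:
            return 403, "text/plain", b"Forbidden\n"
        try:
            return self._route(path)
        except Exception:  # a malformed path is the client's problem
            return 404, "text/plain", b"Not Found\n"

    def _route(self, path: str) -> Tuple[int, str, bytes]:
        parts = [urllib.parse.unquote(p)
                 for p in path.strip("/").split("/") if p != ""]
        if not parts:
            return 404, "text/plain", b"Not Found\n"
        operation, args = parts[0], parts[1:]
        dataset = self.dataset

        if operation == "info" and len(args) == 1:
            database = args[0]
            if database == "kegg" or database in dataset.databases:
                n = len(dataset.databases.get(database, []))
                body = f"{database}             Mock KEGG database\nentries: {n}\n"
                return 200, "text/plain", body.encode("utf-8")
            return 404, "text/plain", b"Not Found\n"

        if operation == "list" and len(args) == 1:
            if args[0] in dataset.databases:
                return 200, "text/plain", dataset.list_body(args[0]).encode("utf-8")
            return 404, "text/plain", b"Not Found\n"

        if operation == "get" and len(args) in (1, 2):
            return self._route_get(args)

        if operation == "find":
            return self._route_find(args)

        if operation in ("conv", "link") and len(args) == 2:
            return self._route_mapping(args)

        if operation == "ddi" and len(args) == 1:
            rows = [
                f"{eid}\tdr:D{(sum(map(ord, eid)) % 99999):05d}\tCI\tmock interaction"
                for eid in args[0].split("+")
                if (e := dataset.index.get(eid)) is not None and e.available
            ]
            if not rows:
                return 404, "text/plain", b"Not Found\n"
            return 200, "text/plain", ("\n".join(rows) + "\n").encode("utf-8")

        return 404, "text/plain", b"Not Found\n"

    def _route_get(self, args: List[str]) -> Tuple[int, str, bytes]:
        quirks = self.quirks
        entry_ids = args[0].split("+")
        field_name = args[1] if len(args) == 2 else None
        if field_name is not None and field_name not in ENTRY_FIELDS:
            return 400, "text/plain", b"Bad Request\n"
        if len(entry_ids) > quirks.max_entries_per_get:
            return 404, "text/plain", b"Not Found\n"
        # The silent-truncation quirk: single-only fields (and, when
        # configured, every grouped request) answer with the first
        # entry only, still status 200.
        if field_name in quirks.single_only_fields:
            entry_ids = entry_ids[:1]
        elif quirks.first_entry_only and len(entry_ids) > 1:
            entry_ids = entry_ids[:1]
        records = []
        for entry_id in entry_ids:
            entry = self.dataset.index.get(entry_id)
            if entry is not None and entry.available:
                records.append(self.dataset.rendition(entry, field_name))
        records = records[:quirks.max_entries_per_get]
        if not records:
            return 404, "text/plain", b"Not Found\n"
        content_type = "image/png" if field_name == "image" else "text/plain"
        return 200, content_type, b"".join(records)

    def _route_find(self, args: List[str]) -> Tuple[int, str, bytes]:
        dataset = self.dataset
        if len(args) not in (2, 3) or args[0] not in dataset.databases:
            return 404, "text/plain", b"Not Found\n"
        database = args[0]
        if len(args) == 2:
            keywords = args[1].split("+")
            hits = dataset.find_by_keywords(database, keywords)
            rows = [f"{e.entry_id}\t{e.name}" for e in hits]
        else:
            value, attribute = args[1], args[2]
            if attribute == "formula":
                hits = dataset.find_by_formula(database, value)
                rows = [f"{e.entry_id}\t{e.formula}" for e in hits]
            elif attribute in ("exact_mass", "mol_weight"):
                bounds = _parse_numeric_value(value)
                if bounds is None:
                    return 400, "text/plain", b"Bad Request\n"
                hits = dataset.find_by_attribute(database, attribute, *bounds)
                rows = [f"{e.entry_id}\t{getattr(e, attribute)}" for e in hits]
            else:
                return 400, "text/plain", b"Bad Request\n"
        body = ("\n".join(rows) + "\n") if rows else "\n"
        return 200, "text/plain", body.encode("utf-8")

    def _route_mapping(self, args: List[str]) -> Tuple[int, str, bytes]:
        dataset = self.dataset
        target, source = args
        if ":" in source:  # entries form
            source_ids = [i for i in source.split("+") if i in dataset.index]
        elif source in dataset.databases:  # database form
            source_ids = [e.entry_id for e in dataset.databases[source]]
        else:
            return 404, "text/plain", b"Not Found\n"
        if not source_ids:
            return 404, "text/plain", b"Not Found\n"
        rows = [f"{eid}\t{target}:{(sum(map(ord, eid)) * 31) % 10 ** 7}"
                for eid in source_ids]
        return 200, "text/plain", ("\n".join(rows) + "\n").encode("utf-8")


def _parse_numeric_value(value: str) -> Optional[Tuple[float, float]]:
    """Parse ``"200-220"`` to a range, or a single number to a ±0.5 band."""
    try:
        if "-" in value:
            low_text, high_text = value.split("-", 1)
            low, high = float(low_text), float(high_text)
        else:
            center = float(value)
            low, high = center - 0.5, center + 0.5
    except ValueError:
        return None
    return (low, high)


class _Handler(BaseHTTPRequestHandler):
    """Routes every GET through :meth:`MockKEGGServer.handle`."""

    def do_GET(self) -> None:  # noqa: N802 - http.server API
        mock: MockKEGGServer = self.server.mock  # type: ignore[attr-defined]
        status, content_type, body = mock.handle(self.path)
        try:
            self.send_response(status)
            self.send_header("Content-Type", content_type)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)
        except (BrokenPipeError, ConnectionResetError):
            pass  # client gave up (timeout tests do this on purpose)

    def log_message(self, *args) -> None:  # silence per-request logging
        pass
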