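"""Fault-tolerant execution of KEGG REST requests.

:class:`KEGGrest` wraps every KEGG REST operation with a retry policy
designed around KEGG's behavior under load: the server temporarily
*blacklists* clients that issue requests too rapidly, answering with a
non-200 status until the client backs off.  Each request is therefore
attempted up to ``n_tries`` times, sleeping ``sleep_time`` seconds after
a failed or timed-out attempt to give the server time to lift the block.

The outcome of a request is never raised as an exception; it is encoded
in the returned :class:`KEGGresponse` as one of three statuses:

``SUCCESS``
    some attempt returned HTTP 200 with a non-empty body (remaining
    attempts are skipped);
``TIMEOUT``
    the final attempt exceeded the per-attempt ``timeout``;
``FAILED``
    anything else, including an HTTP 200 with an empty body — KEGG
    answers 200 for some absent resources, which callers should treat
    as a failure.
"""
from __future__ import annotations

import socket
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Union

from . import urls


class Status(Enum):
    """Outcome of one executed request."""

    SUCCESS = "SUCCESS"
    FAILED = "FAILED"
    TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class RequestPolicy:
    """Retry/timeout/sleep settings for one request.

    ``n_tries``: attempts per request (>= 1).  ``timeout``: seconds an
    attempt may take before it counts as timed out.  ``sleep_time``:
    seconds to wait after a failed or timed-out attempt before retrying,
    giving a blacklisting server time to recover.
    """

    n_tries: int = 3
    timeout: float = 60.0
    sleep_time: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.n_tries, int) or self.n_tries < 1:
            raise ValueError(f"n_tries must be a positive integer, got {self.n_tries!r}")
        if self.timeout <= 0:
            raise ValueError(f"timeout must be positive, got {self.timeout!r}")
        if self.sleep_time < 0:
            raise ValueError(f"sleep_time must be non-negative, got {self.sleep_time!r}")


@dataclass(frozen=True)
class KEGGresponse:
    """What one executed request produced.

    Exactly one of ``text_body``/``binary_body`` is set on SUCCESS
    (binary for image payloads and any body that is not valid UTF-8);
    both are ``None`` on FAILED/TIMEOUT.  ``kegg_url`` is always the
    URL the request was made with.
    """

    status: Status
    kegg_url: urls.KEGGurl
    text_body: Optional[str] = None
    binary_body: Optional[bytes] = None


def _is_binary(content_type: str, body: bytes) -> bool:
    ctype = content_type.lower()
    if ctype.startswith("image/") or ctype.startswith("application/octet"):
        return True
    try:
        body.decode("utf-8")
    except UnicodeDecodeError:
        return True
    return False


class KEGGrest:
    """One wrapper method per KEGG REST operation, plus a test probe.

    Parameters
    ----------
    base_url:
        Endpoint to talk to; defaults to the public KEGG REST server.
        Point it at a local service for offline work and testing.
    policy:
        The :class:`RequestPolicy` applied to every request.
    """

    def __init__(self, base_url: str = urls.BASE_URL,
                 policy: Optional[RequestPolicy] = None) -> None:
        self.base_url = base_url
        self.policy = policy if policy is not None else RequestPolicy()

    # -- core -------------------------------------------------------------

    def execute(self, kegg_url: urls.KEGGurl) -> KEGGresponse:
        """Run one request under the retry policy and classify the outcome.

        Issues at most ``n_tries`` HTTP GET attempts; sleeps
        ``sleep_time`` seconds after every unsuccessful attempt except
        the last.  Never touches the file system and never raises for
        remote failures.
        """
        policy = self.policy
        timed_out = False
        for attempt in range(1, policy.n_tries + 1):
            timed_out = False
            try:
                with urllib.request.urlopen(kegg_url.rendered,
                                            timeout=policy.timeout) as http:
                    body = http.read()
                    content_type = http.headers.get("Content-Type", "")
            except urllib.error.HTTPError:
                pass  # non-200: failed attempt, possibly a blacklist — retry
            except (TimeoutError, socket.timeout):
                timed_out = True
            except urllib.error.URLError as exc:
                timed_out = isinstance(exc.reason, (TimeoutError, socket.timeout))
            else:
                if body:
                    if _is_binary(content_type, body):
                        return KEGGresponse(Status.SUCCESS, kegg_url,
                                            binary_body=body)
                    return KEGGresponse(Status.SUCCESS, kegg_url,
                                        text_body=body.decode("utf-8"))
                # HTTP 200 with an empty body: the entry is absent; count
                # the attempt as failed.
            if attempt < policy.n_tries:
                time.sleep(policy.sleep_time)
        status = Status.TIMEOUT if timed_out else Status.FAILED
        return KEGGresponse(status, kegg_url)

    def test(self, kegg_url: urls.KEGGurl) -> bool:
        """Probe whether ``kegg_url`` would respond successfully.

        Runs the request under the same retry policy but discards the
        payload; nothing is written anywhere.  Unreachable or absent
        resources give ``False``, never an exception.
        """
        return self.execute(kegg_url).status is Status.SUCCESS

    # -- one wrapper per REST operation -----------------------------------

    def info(self, database_name: str) -> KEGGresponse:
        return self.execute(urls.make_info_url(database_name, base_url=self.base_url))

    def list(self, database_name: str) -> KEGGresponse:
        return self.execute(urls.make_list_url(database_name, base_url=self.base_url))

    def get(self, entry_ids: Sequence[str],
            entry_field: Optional[str] = None) -> KEGGresponse:
        return self.execute(urls.make_get_url(entry_ids, entry_field,
                                              base_url=self.base_url))

    def find_keywords(self, database_name: str,
                      keywords: Sequence[str]) -> KEGGresponse:
        return self.execute(urls.make_find_keywords_url(database_name, keywords,
                                                        base_url=self.base_url))

    def find_molecular(self, database_name: str,
                       query: urls.MolecularAttributeQuery) -> KEGGresponse:
        return self.execute(urls.make_find_molecular_url(database_name, query,
                                                         base_url=self.base_url))

    def conv(self, target: str,
             source: Union[str, Sequence[str]]) -> KEGGresponse:
        return self.execute(urls.make_conv_url(target, source,
                                               base_url=self.base_url))

    def link(self, target_database: str,
             source: Union[str, Sequence[str]]) -> KEGGresponse:
        return self.execute(urls.make_link_url(target_database, source,
                                               base_url=self.base_url))

    def ddi(self, drug_entry_ids: Sequence[str]) -> KEGGresponse:
        return self.execute(urls.make_ddi_url(drug_entry_ids,
                                              base_url=self.base_url))
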