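"""Bulk retrieval ("pulling") of KEGG entries into individual files.

A *pull* downloads one or more entries and saves each as its own file,
named ``<entry ID>.<extension>``, inside either a plain directory or a
ZIP archive (chosen by the ``.zip`` suffix of the destination).  The
machinery deals with the quirks of the KEGG server:

* up to 10 entries can be fetched per ``get`` request, but only for the
  flat-file rendition and the aaseq/ntseq/mol/kcf fields — for the
  other fields (and for Brite entries) the server silently returns only
  the first requested entry, so those are fetched one at a time;
* multi-entry response bodies are split into records on the field's
  delimiter convention (``///`` terminator lines for flat files, MOL
  and KCF; ``>`` header lines for FASTA sequence fields);
* when a grouped request fails or comes back incomplete, every entry of
  the group is re-requested individually to maximise the number of
  successful pulls;
* an arbitrary number of IDs is handled by chunking into groups and
  optionally fanning the groups out over worker processes; ZIP archive
  appends are serialised with a cross-process lock because concurrent
  writes would corrupt the archive.

Every pull returns a :class:`PullResult` partitioning the requested IDs
into successful, failed and timed-out.
"""
from __future__ import annotations

import contextlib
import multiprocessing
import os
import time
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

from . import rest as rest_module
from .rest import KEGGrest, Status
from .urls import (EntryFieldSpec, FLAT_FILE, MAX_ENTRIES_PER_GET,
                   resolve_entry_field)

#: Filenames of the pull report written next to a bulk pull.
REPORT_FILENAME = "pull-results.txt"
ABORTED_REPORT_FILENAME = "aborted-pull-results.txt"


# --------------------------------------------------------------------------
# Results and output destinations
# --------------------------------------------------------------------------

@dataclass
class PullResult:
    """Partition of the requested entry IDs by pull outcome.

    The three tuples are disjoint and together contain exactly the IDs
    that were attempted.  ``aborted`` marks a bulk pull halted early by
    the failure-rate threshold (in which case unattempted IDs appear in
    no category).
    """

    successful_entry_ids: Tuple[str, ...] = ()
    failed_entry_ids: Tuple[str, ...] = ()
    timed_out_entry_ids: Tuple[str, ...] = ()
    aborted: bool = False

    @property
    def requested_entry_ids(self) -> Tuple[str, ...]:
        return (self.successful_entry_ids + self.failed_entry_ids
                + self.timed_out_entry_ids)

    def __len__(self) -> int:
        return len(self.requested_entry_ids)

    @property
    def percent_success(self) -> float:
        """``100 * |successful| / |requested|``; undefined when empty."""
        total = len(self)
        if total == 0:
            raise ValueError("percent_success is undefined for an empty pull result")
        return 100.0 * len(self.successful_entry_ids) / total

    def merged_with(self, other: "PullResult") -> "PullResult":
        return PullResult(
            self.successful_entry_ids + other.successful_entry_ids,
            self.failed_entry_ids + other.failed_entry_ids,
            self.timed_out_entry_ids + other.timed_out_entry_ids,
            aborted=self.aborted or other.aborted,
        )


@dataclass(frozen=True)
class OutputSpec:
    """Where pulled entries go: a directory, or a ZIP archive when the
    destination name ends in ``.zip``.  Either is created on demand."""

    destination: str

    def __post_init__(self) -> None:
        if not self.destination:
            raise ValueError("output destination must be non-empty")

    @property
    def archive_mode(self) -> bool:
        return self.destination.endswith(".zip")

    @classmethod
    def coerce(cls, value: Union[str, Path, "OutputSpec"]) -> "OutputSpec":
        if isinstance(value, OutputSpec):
            return value
        return cls(str(value))


# --------------------------------------------------------------------------
# Saving and record splitting
# --------------------------------------------------------------------------

def save_entry(entry_id: str, content: Union[str, bytes],
               output: Union[str, Path, OutputSpec],
               field: EntryFieldSpec = FLAT_FILE,
               lock=None) -> str:
    """Save one entry as ``<entry_id>.<extension>`` and return that name.

    Text content is written UTF-8; bytes are written verbatim.  For ZIP
    destinations the append is guarded by ``lock`` when one is given,
    making concurrent multi-process appends safe.  Note the entry ID is
    used verbatim as the file name — IDs contain a colon, which some
    file systems (not POSIX ones) disallow.
    """
    output = OutputSpec.coerce(output)
    if not content:
        raise ValueError(f"refusing to save empty content for entry {entry_id!r}")
    member = f"{entry_id}.{field.file_extension}"
    data = content.encode("utf-8") if isinstance(content, str) else content
    guard = lock if lock is not None else contextlib.nullcontext()
    if output.archive_mode:
        archive = Path(output.destination)
        archive.parent.mkdir(parents=True, exist_ok=True)
        with guard:
            with zipfile.ZipFile(archive, "a") as zf:
                zf.writestr(member, data)
    else:
        directory = Path(output.destination)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / member).write_bytes(data)
    return member


def split_records(body: str, field: EntryFieldSpec = FLAT_FILE) -> List[str]:
    """Split a multi-entry textual response body into individual records.

    FASTA fields (aaseq/ntseq) start a record at each ``>`` header
    line; flat-file, MOL and KCF bodies end a record at each ``///``
    line, which stays with its record.
    """
    records: List[str] = []
    current: List[str] = []
    if field.name in ("aaseq", "ntseq"):
        for line in body.splitlines(keepends=True):
            if line.startswith(">") and current:
                records.append("".join(current))
                current = []
            current.append(line)
        if current:
            records.append("".join(current))
    else:
        for line in body.splitlines(keepends=True):
            current.append(line)
            if line.strip() == "///":
                records.append("".join(current))
                current = []
        if current and "".join(current).strip():
            records.append("".join(current))
    return records


def separate_entries(body: str, requested_ids: Sequence[str],
                     field: EntryFieldSpec = FLAT_FILE,
                     ) -> Optional[List[Tuple[str, str]]]:
    """Pair the records of a grouped response with the requested IDs.

    Records are matched to IDs positionally, in request order.  When the
    server returned fewer (or more) records than IDs — KEGG silently
    drops entries from some grouped requests — ``None`` is returned to
    signal an incomplete response, which triggers per-entry fallback
    upstream.  Incompleteness is an expected outcome, not an error.
    """
    records = split_records(body, field)
    if len(records) != len(requested_ids):
        return None
    if any(not record.strip() for record in records):
        return None
    return list(zip(requested_ids, records))


def chunk_entry_ids(entry_ids: Sequence[str],
                    group_size: int) -> List[List[str]]:
    """Split IDs into request-sized groups, preserving order.

    Every chunk has exactly ``group_size`` IDs except possibly the last.
    """
    if not isinstance(group_size, int) or group_size < 1:
        raise ValueError(f"group_size must be a positive integer, got {group_size!r}")
    ids = list(entry_ids)
    return [ids[i:i + group_size] for i in range(0, len(ids), group_size)]


# --------------------------------------------------------------------------
# Single request pull (up to 10 entries)
# --------------------------------------------------------------------------

def pull_single(entry_ids: Sequence[str],
                output: Union[str, Path, OutputSpec],
                client: Optional[KEGGrest] = None,
                entry_field: Optional[str] = None,
                force_single_entry: bool = False,
                lock=None) -> PullResult:
    """Pull up to :data:`~keggfetch.urls.MAX_ENTRIES_PER_GET` entries.

    When grouping is allowed (multi-entry field, not forced single, more
    than one ID) a single grouped ``get`` is attempted first; on a
    FAILED response or an incomplete body every entry is re-requested
    one at a time.  A grouped TIMEOUT marks all IDs timed out without
    fallback — the server is unresponsive, not truncating.
    """
    client = client if client is not None else rest_module.KEGGrest()
    ids = [str(i) for i in entry_ids]
    if not 1 <= len(ids) <= MAX_ENTRIES_PER_GET:
        raise ValueError(
            f"pull_single accepts between 1 and {MAX_ENTRIES_PER_GET} entry "
            f"IDs, got {len(ids)}"
        )
    spec = resolve_entry_field(entry_field)
    output = OutputSpec.coerce(output)
    field_name = spec.name or None

    if len(ids) > 1 and spec.supports_multiple and not force_single_entry:
        response = client.get(ids, field_name)
        if response.status is Status.TIMEOUT:
            return PullResult(timed_out_entry_ids=tuple(ids))
        if response.status is Status.SUCCESS and response.text_body is not None:
            pairs = separate_entries(response.text_body, ids, spec)
            if pairs is not None:
                for entry_id, record in pairs:
                    save_entry(entry_id, record, output, spec, lock)
                return PullResult(successful_entry_ids=tuple(ids))
        # FAILED, binary grouped body, or incomplete: fall back per entry.

    successful: List[str] = []
    failed: List[str] = []
    timed_out: List[str] = []
    for entry_id in ids:
        response = client.get([entry_id], field_name)
        if response.status is Status.SUCCESS:
            content = (response.binary_body if response.binary_body is not None
                       else response.text_body)
            save_entry(entry_id, content, output, spec, lock)
            successful.append(entry_id)
        elif response.status is Status.TIMEOUT:
            timed_out.append(entry_id)
        else:
            failed.append(entry_id)
    return PullResult(tuple(successful), tuple(failed), tuple(timed_out))


# --------------------------------------------------------------------------
# Arbitrary-size pulls, single- or multi-process
# --------------------------------------------------------------------------

# Per-worker state set up once per process by the pool initializer.
_worker_state = None


def _init_worker(base_url, policy, output, entry_field, force_single_entry,
                 lock) -> None:
    global _worker_state
    client = KEGGrest(base_url, policy)
    _worker_state = (client, output, entry_field, force_single_entry, lock)


def _pull_chunk(chunk: List[str]) -> PullResult:
    client, output, entry_field, force_single_entry, lock = _worker_state
    return pull_single(chunk, output, client, entry_field,
                       force_single_entry, lock)


def _failure_rate(result: PullResult) -> float:
    total = len(result)
    if total == 0:
        return 0.0
    unsuccessful = len(result.failed_entry_ids) + len(result.timed_out_entry_ids)
    return unsuccessful / total


def pull_multiple(entry_ids: Sequence[str],
                  output: Union[str, Path, OutputSpec],
                  client: Optional[KEGGrest] = None,
                  entry_field: Optional[str] = None,
                  force_single_entry: bool = False,
                  multiprocess: bool = False,
                  n_workers: Optional[int] = None,
                  abort_threshold: Optional[float] = None,
                  progress: Optional[Callable[[int], object]] = None,
                  report_dir: Optional[Union[str, Path]] = None) -> PullResult:
    """Pull an arbitrary number of entries, returning the merged result.

    IDs are chunked into groups of 10 (or 1 when ``force_single_entry``
    is set or the field does not support multi-entry responses), each
    chunk is pulled via :func:`pull_single`, and the per-chunk results
    are merged.  With ``multiprocess=True`` chunks are distributed over
    ``n_workers`` processes (default: all cores); ZIP appends are
    serialised with a shared lock so the archive stays intact.

    ``abort_threshold``, when set, halts the pull as soon as the running
    failure rate (failed + timed out over attempted) exceeds it; the
    returned result is then marked ``aborted`` and covers only the
    attempted IDs.  ``progress`` is called with the number of IDs each
    completed chunk attempted.  When ``report_dir`` is given a
    line-oriented report (``pull-results.txt``, or
    ``aborted-pull-results.txt`` after an abort) is written there.
    """
    client = client if client is not None else rest_module.KEGGrest()
    ids = [str(i) for i in entry_ids]
    if not ids:
        raise ValueError("at least one entry ID is required")
    spec = resolve_entry_field(entry_field)
    group_size = 1 if (force_single_entry or not spec.supports_multiple) \
        else MAX_ENTRIES_PER_GET
    chunks = chunk_entry_ids(ids, group_size)
    output = OutputSpec.coerce(output)

    started = time.monotonic()
    merged = PullResult()
    aborted = False

    if multiprocess:
        workers = n_workers if n_workers is not None else (os.cpu_count() or 1)
        if workers < 1:
            raise ValueError(f"n_workers must be >= 1, got {workers!r}")
        lock = multiprocessing.Lock()
        initargs = (client.base_url, client.policy, output, entry_field,
                    force_single_entry, lock)
        with multiprocessing.Pool(workers, initializer=_init_worker,
                                  initargs=initargs) as pool:
            for result in pool.imap_unordered(_pull_chunk, chunks):
                merged = merged.merged_with(result)
                if progress is not None:
                    progress(len(result))
                if abort_threshold is not None \
                        and _failure_rate(merged) > abort_threshold:
                    aborted = True
                    pool.terminate()
                    break
    else:
        for chunk in chunks:
            result = pull_single(chunk, output, client, entry_field,
                                 force_single_entry)
            merged = merged.merged_with(result)
            if progress is not None:
                progress(len(chunk))
            if abort_threshold is not None \
                    and _failure_rate(merged) > abort_threshold:
                aborted = True
                break

    merged.aborted = aborted
    elapsed = time.monotonic() - started
    if report_dir is not None:
        name = ABORTED_REPORT_FILENAME if aborted else REPORT_FILENAME
        write_pull_report(merged, elapsed, Path(report_dir) / name)
    return merged


def write_pull_report(result: PullResult, elapsed: float,
                      destination: Union[str, Path]) -> Path:
    """Write the line-oriented pull report and return its path.

    The report carries the success percentage (two decimals at most,
    e.g. ``85.51`` or ``100.0``), the elapsed time, and per-category
    counts and ID lists.
    """
    if len(result) == 0:
        raise ValueError("cannot write a report for an empty pull result")
    percent = round(result.percent_success, 2)
    header = "### Aborted pull results ###" if result.aborted \
        else "### Pull results ###"
    lines = [
        header,
        f"Percent success: {percent}",
        f"Elapsed time (seconds): {round(elapsed, 2)}",
        f"Requested entry IDs: {len(result)}",
    ]
    for label, ids in (
        ("Successful", result.successful_entry_ids),
        ("Failed", result.failed_entry_ids),
        ("Timed out", result.timed_out_entry_ids),
    ):
        lines.append(f"{label} entry IDs ({len(ids)}):")
        lines.extend(ids)
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    destination.write_text("\n".join(lines) + "\n")
    return destination
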