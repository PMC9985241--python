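"""Bulk pulling: splitting, saving, chunking, fallback, and reporting."""
from __future__ import annotations

import zipfile
from pathlib import Path

import pytest
from hypothesis import given, strategies as st

from keggfetch import pull
from keggfetch.mock import QuirkConfig
from keggfetch.pull import (OutputSpec, PullResult, chunk_entry_ids,
                            pull_multiple, pull_single, save_entry,
                            separate_entries, split_records,
                            write_pull_report)
from keggfetch.urls import ENTRY_FIELDS, FLAT_FILE, resolve_entry_field

from conftest import client_for


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    ("n_ids", "group_size", "expected_lengths"),
    [(25, 10, [10, 10, 5]), (3, 1, [1, 1, 1]), (10, 10, [10]), (1, 10, [1])],
)
def test_chunk_lengths(n_ids, group_size, expected_lengths):
    ids = [f"cpd:C{i:05d}" for i in range(n_ids)]
    chunks = chunk_entry_ids(ids, group_size)
    assert [len(c) for c in chunks] == expected_lengths
    assert [i for chunk in chunks for i in chunk] == ids


def test_chunking_rejects_non_positive_group_size():
    with pytest.raises(ValueError):
        chunk_entry_ids(["a"], 0)


@given(st.integers(min_value=1, max_value=120),
       st.integers(min_value=1, max_value=15))
def test_chunking_invariants(n_ids, group_size):
    ids = [str(i) for i in range(n_ids)]
    chunks = chunk_entry_ids(ids, group_size)
    assert [i for chunk in chunks for i in chunk] == ids
    assert all(len(c) <= group_size for c in chunks)
    assert all(len(c) == group_size for c in chunks[:-1])


# ---------------------------------------------------------------------------
# Record splitting and pairing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("field_name", [None, "mol", "kcf", "aaseq", "ntseq"])
def test_concatenated_renditions_split_back_into_the_originals(dataset,
                                                               field_name):
    entries = dataset.databases["compound"][:4]
    spec = resolve_entry_field(field_name)
    renditions = [dataset.rendition(e, field_name).decode() for e in entries]
    body = "".join(renditions)
    assert split_records(body, spec) == renditions


def test_separate_entries_pairs_records_with_request_order(dataset):
    entries = dataset.databases["compound"][:2]
    ids = [e.entry_id for e in entries]
    body = "".join(dataset.rendition(e, None).decode() for e in entries)
    pairs = separate_entries(body, ids, FLAT_FILE)
    assert pairs is not None
    assert [i for i, _ in pairs] == ids
    assert pairs[0][1] == dataset.rendition(entries[0], None).decode()


def test_separate_entries_signals_incomplete_responses(dataset):
    entries = dataset.databases["compound"][:2]
    ids = [e.entry_id for e in entries]
    only_first = dataset.rendition(entries[0], None).decode()
    assert separate_entries(only_first, ids, FLAT_FILE) is None


def test_single_record_single_id_pairs_whole_body(dataset):
    entry = dataset.databases["compound"][0]
    body = dataset.rendition(entry, None).decode()
    assert separate_entries(body, [entry.entry_id], FLAT_FILE) == \
        [(entry.entry_id, body)]


# ---------------------------------------------------------------------------
# Saving
# ---------------------------------------------------------------------------

def test_save_entry_to_directory_uses_id_and_extension(tmp_path):
    member = save_entry("cpd:C00001", "mol text\n", tmp_path / "kegg-entries",
                        ENTRY_FIELDS["mol"])
    assert member == "cpd:C00001.mol"
    assert (tmp_path / "kegg-entries" / member).read_text() == "mol text\n"


def test_save_entry_appends_binary_member_to_zip(tmp_path):
    archive = tmp_path / "out.zip"
    payload = b"\x89PNG\r\n\x1a\nrest"
    member = save_entry("cpd:C00001", payload, archive, ENTRY_FIELDS["image"])
    with zipfile.ZipFile(archive) as zf:
        assert zf.testzip() is None
        assert zf.read(member) == payload
    assert member == "cpd:C00001.image"


def test_save_entry_rejects_empty_content(tmp_path):
    with pytest.raises(ValueError):
        save_entry("x", "", tmp_path / "d")


def test_output_spec_zip_suffix_rule():
    assert OutputSpec("a/b.zip").archive_mode is True
    assert OutputSpec("a/b").archive_mode is False
    with pytest.raises(ValueError):
        OutputSpec("")


# ---------------------------------------------------------------------------
# Single pulls
# ---------------------------------------------------------------------------

def test_pull_single_saves_every_entry_byte_exactly(make_server, dataset,
                                                    tmp_path):
    server = make_server()
    entries = dataset.databases["compound"][:2]
    ids = [e.entry_id for e in entries]
    result = pull_single(ids, tmp_path / "entries", client_for(server))
    assert result.successful_entry_ids == tuple(ids)
    assert result.failed_entry_ids == () and result.timed_out_entry_ids == ()
    for entry in entries:
        saved = (tmp_path / "entries" / f"{entry.entry_id}.txt").read_bytes()
        assert saved == dataset.rendition(entry, None)
    assert len(server.request_paths("/get/")) == 1  # one grouped request


def test_truncated_grouped_response_triggers_per_entry_fallback(make_server,
                                                                dataset,
                                                                tmp_path):
    server = make_server(QuirkConfig(first_entry_only=True))
    ids = [e.entry_id for e in dataset.databases["compound"][:2]]
    result = pull_single(ids, tmp_path / "entries", client_for(server))
    assert result.successful_entry_ids == tuple(ids)
    # one grouped attempt plus one request per entry
    assert len(server.request_paths("/get/")) == 3


def test_failed_grouped_request_falls_back_per_entry(make_server, dataset,
                                                     tmp_path):
    server = make_server(QuirkConfig(script=[403, 403]))
    ids = [e.entry_id for e in dataset.databases["compound"][:2]]
    result = pull_single(ids, tmp_path / "entries",
                         client_for(server, n_tries=1))
    # the grouped attempt and the first fallback single consume the two
    # scripted failures; the second fallback single succeeds normally
    assert set(result.requested_entry_ids) == set(ids)
    assert len(result.successful_entry_ids) == 1
    assert len(result.failed_entry_ids) == 1


def test_timed_out_single_pull_saves_nothing(make_server, dataset, tmp_path):
    server = make_server(QuirkConfig(response_delay=0.5))
    entry_id = dataset.databases["compound"][0].entry_id
    result = pull_single([entry_id], tmp_path / "entries",
                         client_for(server, n_tries=1, timeout=0.1))
    assert result.timed_out_entry_ids == (entry_id,)
    assert not (tmp_path / "entries").exists()


def test_pull_single_rejects_more_than_ten_ids(make_server, tmp_path):
    server = make_server()
    with pytest.raises(ValueError):
        pull_single([f"cpd:C{i:05d}" for i in range(11)], tmp_path / "d",
                    client_for(server))


# ---------------------------------------------------------------------------
# Multiple pulls
# ---------------------------------------------------------------------------

def test_pull_multiple_chunks_at_the_request_cap(make_server, dataset,
                                                 tmp_path):
    server = make_server()
    ids = [e.entry_id for e in dataset.databases["compound"][:25]]
    result = pull_multiple(ids, tmp_path / "entries", client_for(server))
    assert set(result.successful_entry_ids) == set(ids)
    gets = server.request_paths("/get/")
    assert len(gets) == 3
    assert all(p.split("/")[2].count("+") <= 9 for p in gets)


def test_single_only_field_forces_one_entry_per_request(make_server, dataset,
                                                        tmp_path):
    server = make_server()
    entries = dataset.databases["compound"][:3]
    ids = [e.entry_id for e in entries]
    result = pull_multiple(ids, tmp_path / "entries", client_for(server),
                           entry_field="image")
    assert set(result.successful_entry_ids) == set(ids)
    gets = server.request_paths("/get/")
    assert len(gets) == 3
    assert all("+" not in p for p in gets)
    for entry in entries:
        saved = (tmp_path / "entries" / f"{entry.entry_id}.image").read_bytes()
        assert saved == dataset.rendition(entry, "image")
        assert saved.startswith(b"\x89PNG")


def test_force_single_entry_issues_one_id_per_get(make_server, dataset,
                                                  tmp_path):
    server = make_server()
    ids = [e.entry_id for e in dataset.databases["compound"][:5]]
    pull_multiple(ids, tmp_path / "entries", client_for(server),
                  force_single_entry=True)
    assert all("+" not in p for p in server.request_paths("/get/"))


def test_single_and_multi_process_pulls_are_equivalent(make_server, dataset,
                                                       tmp_path):
    server = make_server()
    ids = [e.entry_id for e in dataset.databases["compound"]]
    client = client_for(server)
    sp = pull_multiple(ids, tmp_path / "sp", client)
    mp = pull_multiple(ids, tmp_path / "mp.zip", client, multiprocess=True,
                       n_workers=3)
    assert set(sp.successful_entry_ids) == set(mp.successful_entry_ids)
    assert set(sp.failed_entry_ids) == set(mp.failed_entry_ids)
    sp_members = {p.name for p in (tmp_path / "sp").iterdir()}
    with zipfile.ZipFile(tmp_path / "mp.zip") as zf:
        assert zf.testzip() is None
        mp_members = set(zf.namelist())
        assert len(mp_members) == len(mp.successful_entry_ids)
        for entry in dataset.databases["compound"][:5]:
            assert zf.read(f"{entry.entry_id}.txt") == \
                dataset.rendition(entry, None)
    assert sp_members == mp_members


def test_unavailable_entries_partition_into_failed(make_server, dataset,
                                                   tmp_path):
    server = make_server()
    ids = [e.entry_id for e in dataset.databases["brite"]]
    result = pull_multiple(ids, tmp_path / "entries",
                           client_for(server, n_tries=1),
                           entry_field="json")
    unavailable = {e.entry_id for e in dataset.databases["brite"]
                   if not e.available}
    assert set(result.failed_entry_ids) == unavailable
    assert set(result.successful_entry_ids) == set(ids) - unavailable
    assert sorted(result.requested_entry_ids) == sorted(ids)


def test_abort_threshold_halts_before_completing_all_chunks(make_server,
                                                            dataset,
                                                            tmp_path):
    server = make_server()
    bad = [f"cpd:C9{i:04d}" for i in range(10)]
    good = [e.entry_id for e in dataset.databases["compound"][:10]]
    result = pull_multiple(bad + good, tmp_path / "entries",
                           client_for(server, n_tries=1),
                           abort_threshold=0.25, report_dir=tmp_path)
    assert result.aborted
    assert len(result) < 20  # halted before the second chunk
    report = tmp_path / pull.ABORTED_REPORT_FILENAME
    assert report.exists()
    assert "Aborted" in report.read_text()


def test_blacklist_monotonicity_under_deterministic_cooldown(make_server,
                                                             dataset,
                                                             tmp_path):
    cooldown = 0.1
    ids = [e.entry_id for e in dataset.databases["compound"][:30]]
    server = make_server(QuirkConfig(blacklist_cooldown=cooldown))
    rushed = pull_multiple(ids, tmp_path / "rushed",
                           client_for(server, n_tries=3, sleep_time=0.0))
    server.reset(QuirkConfig(blacklist_cooldown=cooldown))
    patient = pull_multiple(ids, tmp_path / "patient",
                            client_for(server, n_tries=3, sleep_time=0.15))
    assert patient.percent_success == 100.0
    assert rushed.percent_success < patient.percent_success


# ---------------------------------------------------------------------------
# Results and reports
# ---------------------------------------------------------------------------

def _result(n_ok, n_failed, n_timed_out):
    return PullResult(
        tuple(f"br:br{i:05d}" for i in range(n_ok)),
        tuple(f"br:brf{i:04d}" for i in range(n_failed)),
        tuple(f"br:brt{i:04d}" for i in range(n_timed_out)),
    )


def test_percent_success_arithmetic():
    assert round(_result(118, 20, 0).percent_success, 2) == 85.51
    assert _result(5, 0, 0).percent_success == 100.0
    with pytest.raises(ValueError):
        _result(0, 0, 0).percent_success


def test_report_prints_percent_to_two_decimals(tmp_path):
    path = write_pull_report(_result(118, 20, 0), elapsed=12.3,
                             destination=tmp_path / "pull-results.txt")
    text = path.read_text()
    assert "Percent success: 85.51" in text
    assert "Successful entry IDs (118):" in text
    assert "Failed entry IDs (20):" in text
    assert "Timed out entry IDs (0):" in text
    assert "Elapsed time (seconds): 12.3" in text


def test_report_of_full_success_prints_100(tmp_path):
    path = write_pull_report(_result(7, 0, 0), 1.0, tmp_path / "r.txt")
    assert "Percent success: 100.0" in path.read_text()


def test_report_of_empty_result_raises(tmp_path):
    with pytest.raises(ValueError):
        write_pull_report(PullResult(), 0.0, tmp_path / "r.txt")


def test_merge_concatenates_partitions():
    merged = _result(2, 1, 0).merged_with(PullResult((), (), ("x",)))
    assert len(merged.successful_entry_ids) == 2
    assert merged.timed_out_entry_ids == ("x",)
    assert len(merged) == 4
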