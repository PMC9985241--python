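# keggfetch

Fault-tolerant, scriptable access to the [KEGG](https://www.kegg.jp)
REST API from Python and the shell.

KEGG (the Kyoto Encyclopedia of Genes and Genomes) organises genomic,
biomolecular and metabolic knowledge as databases of *entries*
(compounds, genes, pathways, drugs, Brite hierarchies, …), each keyed
by an entry ID such as `cpd:C00001`. The data is exposed through a REST
web API driven entirely by GET URLs — but constructing those URLs is
fiddly, responses need post-processing, and the server both limits
request sizes and temporarily *blacklists* clients that ask too fast.
`keggfetch` packages all of that:

- **URL construction with validation** for all seven REST operations
  (`info`, `list`, `get`, `find`, `conv`, `link`, `ddi`), enforcing the
  10-entry cap of the `get` operation and the 4000-character limit on
  the request line before anything is sent.
- **Retry-aware execution**: each request is tried up to `n_tries`
  times (default 3) with a per-attempt `timeout` (default 60 s) and a
  configurable `sleep_time` between unsuccessful attempts, so transient
  blacklisting resolves itself. The outcome is a `KEGGresponse` with a
  three-valued status — `SUCCESS`, `FAILED` or `TIMEOUT` — plus the text
  or binary body and the originating URL.
- **Clean entry-ID lists** from the `list`/`find` operations (metadata
  stripped) or from local files.
- **Bulk pulling** of an arbitrary number of entries into individual
  files — a plain directory, or a ZIP archive when the destination name
  ends in `.zip` — single-process or fanned out over worker processes
  (ZIP appends are lock-serialised so the archive cannot be corrupted).
  Grouped responses are split into records on their delimiters
  (`///` terminator lines; `>` FASTA headers) and matched to the
  requested IDs; if a grouped request fails or comes back silently
  truncated, every entry is re-requested one at a time. Each pull
  returns a `PullResult` partitioning the requested IDs into
  successful / failed / timed-out, and bulk pulls write a plain-text
  report with counts, ID lists, the success percentage and elapsed time.
- **An offline mock KEGG service** (`keggfetch.mock`): a seeded
  synthetic dataset served over a local HTTP endpoint that speaks the
  KEGG path grammar, including its empirically observed quirks
  (10-entry cap, single-only entry fields, silent truncation,
  blacklisting, request-line length rejection). Everything above is
  testable without network access.

## Worked example

Pull a whole (synthetic) compound database into a ZIP archive
(`examples/bulk_pull.py`; drop the mock server and the `base_url`
argument to talk to live KEGG):

```python
from keggfetch import entry_ids
from keggfetch.mock import MockKEGGServer, generate_dataset
from keggfetch.pull import pull_multiple
from keggfetch.rest import KEGGrest, RequestPolicy

dataset = generate_dataset(seed=1, sizes={"compound": 50})
with MockKEGGServer(dataset) as server:
    client = KEGGrest(server.base_url, RequestPolicy(timeout=10))
    ids = entry_ids.from_database("compound", client)
    result = pull_multiple(ids, "kegg-entries.zip", client, report_dir=".")
```

Output:

```
pulled 50 entries in 5 grouped requests
successful=50 failed=0 timed_out=0 percent_success=100.0
```

The 50 IDs travelled as 5 grouped `get` requests of 10 entries each;
every entry was saved as its own `<id>.txt` member of the archive, and
`pull-results.txt` records the partition and the success percentage
(`100.0` here; a pull of 138 entries of which 20 are unavailable would
report `85.51`).

The same pull from the shell:

```sh
kegg-fetch entry-ids database compound | \
    kegg-fetch pull entry-ids --multi-process --n-workers=4 \
        --output=kegg-entries.zip --sleep-time=5.0
```

`kegg-fetch rest` and `kegg-fetch entry-ids` cover the individual
operations (`kegg-fetch rest find drug --exact-mass=200
--exact-mass=220`, `kegg-fetch rest get cpd:C00001 --test`, …). Exit
codes: 0 success, 1 usage/validation error, 2 aborted pull (failure
rate exceeded `--abort-threshold`), 3 pull with no successful entry.

For live KEGG use with multiprocessing, a generous `--sleep-time` (5–10
seconds) maximises the success percentage at negligible cost in total
pull time; re-run the failed IDs afterwards, since entries can also
fail transiently.

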