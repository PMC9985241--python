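# Methods

## The access model

KEGG's REST API is a set of seven GET operations addressed purely by
URL path: `info`, `list`, `get`, `find`, `conv`, `link` and `ddi`, with
multi-valued segments joined by `+`. `keggfetch` treats a request as a
three-stage pipeline — construct and validate the URL, execute it under
a retry policy, post-process the body — and keeps the stages in
separate modules (`urls`, `rest`, `entry_ids`/`pull`) so each is usable
and testable on its own.

Two server-side limits are enforced at construction time rather than
discovered as opaque failures:

- the `get` operation accepts at most **10 entry IDs** per request;
- the whole request line is limited, so URLs longer than **4000
  characters** (scheme and host included — the server's limit is on the
  request line, which contains the full URL) are refused with advice to
  split the request. The bound is inclusive: a 4000-character URL
  constructs, a 4001-character one raises.

Database names are validated for shape (non-empty, no whitespace or
reserved characters) but not against a closed vocabulary: KEGG adds
organism codes continuously, so unknown names pass through with a
warning and the registry is extensible at run time.

## Retry, timeout, blacklisting

KEGG temporarily blacklists clients that issue requests too rapidly,
answering with a non-200 status until the client backs off. The client
therefore never trusts a single attempt: each request is tried up to
`n_tries` times (default 3), each attempt bounded by `timeout` seconds
(default 60), with `sleep_time` seconds (default 0) slept after every
unsuccessful attempt except the last. Any non-200 status is treated as
retryable — the specific status code KEGG uses for blacklisting is not
documented, and retrying a genuinely permanent failure costs at most
`n_tries - 1` extra attempts. An HTTP 200 with an empty body counts as
a failed attempt: KEGG answers 200 for some absent resources. The final
status is `SUCCESS` as soon as any attempt yields a 200 with a
non-empty body, otherwise `TIMEOUT` if the *final* attempt timed out
and `FAILED` otherwise — the simplest contract consistent with a
three-valued status. Bodies whose content type is an image (or that do
not decode as UTF-8) are kept as bytes; everything else is text.

The `test` probe answers "would this URL respond?" by running the same
retry loop and discarding the payload; a dedicated lightweight HTTP
method is deliberately not used, so the probe's answer reflects exactly
what a real retrieval would experience.

## Pulling

A pull saves each entry as `<entry id>.<extension>` — the extension is
the entry-field name, or `txt` for the default flat-file rendition —
into a directory, or into a ZIP archive when the destination ends in
`.zip` (either is created on demand). Entry IDs are used verbatim as
file names; they contain a colon, which is fine on POSIX file systems
but not on all others — a documented caveat rather than an escaping
scheme.

Grouped `get` responses are split into records by delimiter
convention: flat-file, MOL and KCF bodies split on lines consisting of
`///` (the terminator stays with its record); FASTA bodies (aaseq,
ntseq) split on lines starting with `>`. Records are paired with the
requested IDs positionally, in request order, with no content-based ID
sniffing — when the record count does not match the request, the
response is treated as incomplete and every entry of the group is
re-requested individually. This fallback also covers the server's
silent-truncation behavior: for the `image`, `conf`, `kgml` and `json`
entry fields (and for Brite entries) a grouped request returns only the
first entry with status 200 and no other indication. Those fields are
marked single-only in the field registry, so they are never grouped in
the first place; `force_single_entry` extends the same treatment to
Brite IDs pulled from a file, and the CLI applies it automatically when
the database named on the command line is `brite`. A grouped request
that *times out* marks all its IDs timed out without fallback: an
unresponsive server is not a truncating one, and hammering it with ten
single requests would make matters worse.

Arbitrary-size pulls chunk the ID list into groups of 10 (1 when
forced single), pull each group, and merge the per-group results into
one `PullResult` whose three categories always partition the attempted
IDs. Chunks can be distributed over worker processes; writing into a
directory needs no coordination (each file is written wholly within one
process), but a ZIP archive is a single file, so archive appends are
serialised with a cross-process lock held only around the open-append-
close critical section. An optional `abort_threshold` halts the pull
when the running failure rate (failed + timed out over attempted)
exceeds it — disabled by default, since halting is an option rather
than a policy — and the report is then written under the distinct name
`aborted-pull-results.txt`. Reports are line-oriented text: success
percentage (rounded to at most two decimals, so `85.51` and `100.0`
print as such), elapsed seconds, and per-category counts and ID lists.
Progress reporting is a pluggable callback — a console bar in the CLI,
silent by default in library use.

## The mock KEGG service

`keggfetch.mock` exists so that every behavior above is testable
offline. `generate_dataset(seed, sizes, unavailable)` is a pure
function of its arguments: per database it draws entry names, chemical
formulas, exact masses (uniform on 100–500 Da), molecular weights, and
amino-acid/nucleotide sequences from a `random.Random` seeded per
`(seed, database)`, and derives every rendition (flat file, FASTA, MOL,
KCF, KGML, JSON, conf, and a small valid PNG whose pixel colour is a
function of the entry ID) deterministically from those attributes.
Identical seeds give byte-identical datasets, which makes the dataset a
byte-exact oracle for what a pull should have saved. A configurable
number of trailing entries per database can be marked *listed but
unavailable* — they appear in `list` output yet every `get` for them
fails, emulating the permanently absent entries observed in the real
Brite database.

The server (stdlib `ThreadingHTTPServer`) routes the KEGG path grammar
over the dataset and reproduces the server-side quirks, each
reconfigurable per test via `QuirkConfig`: the 10-entry `get` cap
(non-200 beyond it), silent first-entry truncation for single-only
fields (optionally for all grouped requests), request-line length
rejection, a fixed response delay (for timeout tests), a scripted
per-request outcome sequence (for retry tests), and blacklisting either
probabilistic with a seeded RNG or deterministic: a request arriving
within `cooldown` seconds of the previous request gets 403, and every
request — accepted or rejected — resets the clock. The deterministic
cooldown makes the sleep-time/success-rate relationship reproducible:
with 3 tries and `sleep_time >= cooldown` every request succeeds by its
second attempt (100 % success), while `sleep_time = 0` leaves all but
the first burst blacklisted.

What the mock does **not** emulate: real KEGG content (bodies are
structurally faithful but biologically meaningless), the real server's
load-dependent and nondeterministic blacklisting, HTTPS, and weekly
data updates. Passing tests therefore demonstrate the correctness of
the client logic — validation, retry accounting, splitting, fallback,
partitioning, file fidelity, multiprocess safety — not live-KEGG
throughput or success rates, which depend on network conditions and
server policy. One consequence of the stack's own rules deserves note:
an existing-but-empty database's `list` response is served as a single
newline rather than a zero-byte body, because an empty 200 is
classified as FAILED by the client (matching the treatment of absent
entries), while an empty database should parse to an empty ID list.

## Problem sizes and numerical choices

The bundled verification runs at sizes chosen to exercise every code
path while staying comfortably reproducible on a laptop: shared test
databases of 8–60 entries (with a 12-entry Brite-like database, 3 of
them unavailable), 1,000 entries for byte-fidelity, 500 entries for the
single-process/4-worker equivalence check, 200 randomized scenarios for
the partition invariant, a 138-entry database with 20 unavailable for
report arithmetic, and cooldowns of ~0.1 s standing in for the
multi-second sleeps appropriate against live KEGG. Timeout tests use
sub-second timeouts against a deliberately delayed server. None of
these sizes affect the logic being verified; they scale the same
machinery that a live pull of a whole KEGG database uses.

## Known limitations

- The exact delimiters live KEGG uses for multi-entry MOL/KCF bodies
  are encoded here as `///` terminator lines; the mock follows the same
  convention, so the splitter is verified against the fixture, not
  against the live server.
- No caching, no resume-from-partial-archive, no deduplication of
  requested IDs, and no exponential backoff (the sleep is fixed by
  design).
- File names use entry IDs verbatim (colon included).
- The ID-record pairing is positional; a server that reordered records
  within a grouped response would be mis-paired (KEGG preserves request
  order).
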