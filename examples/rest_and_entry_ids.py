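"""Run REST operations and extract clean entry-ID lists, fully offline.

A seeded synthetic KEGG dataset is served by a local endpoint speaking
the real KEGG path grammar, so the whole client stack can be exercised
without network access; point ``KEGGrest`` at the real endpoint (the
default) for live use.
"""
from keggfetch import entry_ids, urls
from keggfetch.mock import MockKEGGServer, generate_dataset
from keggfetch.rest import KEGGrest, RequestPolicy
from keggfetch.urls import MolecularAttributeQuery

dataset = generate_dataset(seed=1, sizes={"compound": 40, "drug": 25})

with MockKEGGServer(dataset) as server:
    client = KEGGrest(server.base_url, RequestPolicy(n_tries=3, timeout=10))

    response = client.list("compound")
    print(f"list compound -> status {response.status.value}, "
          f"{len(response.text_body.splitlines())} raw table lines")
    print("first raw line:", response.text_body.splitlines()[0])

    ids = entry_ids.from_database("compound", client)
    print(f"parsed entry IDs (metadata stripped): {len(ids)}, "
          f"first: {ids[0]}")

    query = MolecularAttributeQuery("exact_mass", (200, 300))
    hits = entry_ids.from_molecular_attribute("drug", query, client)
    print(f"drug entries with exact mass in [200, 300]: {len(hits)}")

    probe = client.test(urls.make_get_url([ids[0]], base_url=server.base_url))
    print(f"test probe for {ids[0]}: {probe}")

print("\nThe raw list body carries one '<id>\\t<metadata>' line per entry; "
      "the entry_ids helpers return only the IDs, ready to feed a pull.")
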