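"""Construct and validate KEGG REST URLs without touching the network.

Every KEGG API operation is a GET URL; these builders render it and
refuse invalid argument combinations (too many entry IDs, a single-only
entry field with several IDs, an over-long request line) before any
request could be made.
"""
from keggfetch import urls
from keggfetch.urls import MolecularAttributeQuery

examples = [
    urls.make_list_url("hsa"),
    urls.make_get_url(["cpd:C00001", "cpd:C00002"]),
    urls.make_get_url(["hsa:10458"], entry_field="aaseq"),
    urls.make_find_keywords_url("compound", ["glucose"]),
    urls.make_find_molecular_url(
        "drug", MolecularAttributeQuery("exact_mass", (200, 220))),
    urls.make_conv_url("ncbi-geneid", "hsa"),
    urls.make_link_url("pathway", ["hsa:10458"]),
    urls.make_ddi_url(["dr:D00564"]),
]
for kegg_url in examples:
    print(f"{kegg_url.operation:<15} {kegg_url.rendered}")

# Invalid combinations fail fast, with feedback, before any request:
for bad in (
    lambda: urls.make_get_url([f"cpd:C{i:05d}" for i in range(11)]),
    lambda: urls.make_get_url(["cpd:C00001", "cpd:C00002"], "image"),
    lambda: urls.make_find_keywords_url("compound", ["k" * 4000]),
):
    try:
        bad()
    except urls.KEGGurlError as exc:
        print(f"rejected:       {exc}")

print("\nEach line is a ready-to-request KEGG REST URL; the rejected ones "
      "show the validation that runs before any network activity.")
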