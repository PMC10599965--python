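"""Directional (up/down) signatures from a GMT file.

GMT has no native directionality, so a two-part signature is written as two
lines sharing a stem: ``response.up`` and ``response.dn``.  After pairing,
the down half is scored in opposition to the up half: cells expressing the
up-genes highly and the down-genes lowly score positive.
"""

import tempfile

from smoothscore import pair_updown_sets, rank_profile, read_gmt, score_rbo, score_ssgsea

gmt = "response.up\t\tgeneA\tgeneB\tgeneC\nresponse.dn\t\tgeneD\tgeneE\n"
with tempfile.NamedTemporaryFile("w", suffix=".gmt", delete=False) as fh:
    fh.write(gmt)
    path = fh.name

sets = pair_updown_sets(read_gmt(path))
(sig,) = sets
print(f"parsed {sig.name!r}: mode={sig.mode}, up={sorted(sig.up_genes)}, "
      f"down={sorted(sig.down_genes)}")

gene_ids = ["geneA", "geneB", "geneC", "geneD", "geneE", "geneF", "geneG", "geneH"]
responding = rank_profile([9, 8, 7, 0, 1, 3, 4, 5], gene_ids)   # up high, down low
opposite = rank_profile([0, 1, 2, 9, 8, 3, 4, 5], gene_ids)     # reversed pattern

for name, profile in (("responding cell", responding), ("opposite cell", opposite)):
    print(f"{name:>16}: ssGSEA={score_ssgsea(profile, sig):+7.3f}  "
          f"RBO={score_rbo(profile, sig):+5.3f}")

# The responding cell scores positive with both functions; the cell with the
# inverted pattern scores negative — the two halves of the signature pull
# the score in opposite directions.
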