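"""Tally cross-species direction concordance for the 23 published potato genes.

Each selected potato drought gene carries one direction symbol per homologue
(Arabidopsis, rice), relative to the potato response: same direction
(up/down arrow), no change (dash), no data (nd), no homologue, or opposite.
The tabulation counts in how many genes the drought response is conserved
across species.
"""

from droughtdex import published_potato_calls, tabulate_concordance

table = tabulate_concordance(published_potato_calls())

print(f"direction calls: {table.n_calls}")
for category, count in sorted(table.counts.items()):
    print(f"  {category:30s} {count}")
print(f"  {'opposite in >=1 species':30s} {table.opposite_any}")

# Expected output: of 23 genes, 6 are conserved in potato + Arabidopsis +
# rice, 9 in rice only, 1 in Arabidopsis only, and 2 genes move in the
# opposite direction in one species. The four primary categories partition
# the 23 calls; the opposite tally overlaps them.
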