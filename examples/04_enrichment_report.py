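"""Composition arithmetic: fold enrichment between two community profiles.

Compares a taxon's relative abundance in an input community with its
abundance after droplet cultivation, the arithmetic behind statements like
"a 22-fold increase over the input community".
"""

import pandas as pd

from dropgrow import CompositionTable, fold_enrichment, unique_taxa_count
from dropgrow.reporting import enrichment_table

before = CompositionTable(pd.DataFrame(
    {"sample_id": "input_stool",
     "taxon": ["P_faecium", "M_smithii", "Bacteroides", "other"],
     "abundance_pct": [0.8, 0.4, 40.0, 58.8]}))
after = CompositionTable(pd.DataFrame(
    {"sample_id": "droplet_enrichment",
     "taxon": ["P_faecium", "M_smithii", "Bacteroides", "other"],
     "abundance_pct": [17.8, 6.0, 30.0, 46.2]}))

print(f"taxa in input: {unique_taxa_count(before, 'input_stool')}, "
      f"after enrichment: {unique_taxa_count(after, 'droplet_enrichment')}\n")

report = enrichment_table(before, after)
print(report.to_string(index=False))

print(f"\nP. faecium fold enrichment: {fold_enrichment(17.8, 0.8):.2f} "
      f"(reported as {round(fold_enrichment(17.8, 0.8))}-fold)")
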