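"""GI quantification ratios on generated fixtures.

Gastric emptying (% of total gut radiant efficiency outside the stomach),
stool water content (% of wet weight lost on drying), whole-mount nerve
density (NerveArea/TotalArea) and IGVE density (LabeledGanglia/TotalArea).
Printed: each ratio next to the fixture's ground truth — they must agree to
numerical precision because the ratios are deterministic arithmetic.
"""

from drgcal import NerveField, generate_quant_fixtures, igve_density, nerve_density
from drgcal.quant import emptying_table, water_content_table

fx = generate_quant_fixtures(seed=1)
gt = fx["ground_truth"]

emp = emptying_table(fx["regions"])
print(f"sample s1 gastric emptying: {emp['emptying_pct'].iloc[0]:.2f}% "
      f"(truth {gt['emptying_pct'][0]:.2f}%), "
      f"retention {emp['retention_pct'].iloc[0]:.2f}%")

wat = water_content_table(fx["stools"])
print(f"sample s1 stool water content: {wat['water_content_pct'].iloc[0]:.2f}% "
      f"(truth {gt['water_content_pct'][0]:.2f}%)")

field = NerveField(fx["nerve_mask"], fx["ganglia_count"])
print(f"nerve density: {nerve_density(field):.4f} (truth {gt['nerve_density']:.4f})")
print(f"IGVE density: {igve_density(field)['igve_per_1000px2']:.3f} per 1000 px2 "
      f"({fx['ganglia_count']} ganglia in {fx['field_area_px2']} px2)")
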