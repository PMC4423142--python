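"""Use the published pIC50 equations and the packaged compound table.

The two final equations ship with their printed coefficients; the compound
table carries the 30 L-tyrosine derivatives with experimental and
model-predicted MMP-2 inhibition (pIC50 = -log10 IC50, higher = more potent).
"""

from tyroqsar import load_equation, load_table1, predict_published

eq1 = load_equation("eq1_mlr")
print("general MLR equation (5 descriptors):")
terms = " ".join(f"{c:+.3f}·{d}" for d, c in zip(eq1.descriptors, eq1.coefficients))
print(f"  pIC50 = {eq1.intercept:.3f} {terms}")
print(f"  stats: {eq1.stats}")

example = {"IC1": 2.8, "Mor24m": 0.6, "RDF115m": 4.0, "SP20": 5.0, "Mor15e": 0.3}
print(f"\nexample descriptor values {example}")
print(f"predicted pIC50 = {predict_published('eq1_mlr', example):.3f}")

records = load_table1(as_frame=True)
records["abs_dev_mlr"] = (records["pic50_exp"] - records["pic50_mlr"]).abs()
print(f"\npackaged compound table: {len(records)} records")
print(records.nlargest(3, "pic50_exp")[
    ["compound", "r1", "r2", "r3", "pic50_exp", "pic50_mlr", "pic50_gapls"]
].to_string(index=False))
print(f"max |experimental - MLR predicted| over 30 compounds: "
      f"{records['abs_dev_mlr'].max():.2f} pIC50 units")
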