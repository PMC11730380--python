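"""Assign a severity level to a predicted interaction from structure.

If drug C is structurally similar to a drug A that is already known to
interact with drug B, the C-B interaction is expected to carry a similar
severity. Similarity is the weighted Tanimoto + Dice + cosine score over
Morgan fingerprints; the transferred 1-100 score is banded into
MINOR (1-30) / MODERATE (31-60) / MAJOR (61-100).
"""

from mdfldrr import fingerprint_from_smiles, infer_severity, mssd

smiles = {
    "amitriptyline": "CN(C)CCC=C1c2ccccc2CCc2ccccc21",
    "nortriptyline": "CNCCC=C1c2ccccc2CCc2ccccc21",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
}
fps = {name: fingerprint_from_smiles(s) for name, s in smiles.items()}

sim = mssd(fps["nortriptyline"], fps["amitriptyline"])
print(f"nortriptyline vs amitriptyline structural similarity: {sim:.3f}")
print(f"nortriptyline vs aspirin similarity: {mssd(fps['nortriptyline'], fps['aspirin']):.3f}")

# known: amitriptyline-irbesartan interaction carries severity score 55 (MODERATE)
assessment = infer_severity(
    drugC="nortriptyline",
    drugB="irbesartan",
    known=[("amitriptyline", 55.0)],
    fingerprints=fps,
)
print(f"\ninferred nortriptyline-irbesartan severity: "
      f"{assessment.score:.0f} ({assessment.level})")
print("the score is the similarity-weighted mean of the known interactors'")
print("severities; the level is its band on the 1-100 scale.")
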