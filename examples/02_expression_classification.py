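"""Classify genes and reactions from a scenario expression contrast.

Generates the synthetic MG E1-vs-E2 contrast (log2 fold-changes drawn from
class-conditional distributions), calls genes up/down/neutral at |log2FC|
≥ 1 with a significance requirement, propagates the calls through GPR
rules, and maps reaction classes to soft penalty weights.
"""

from collections import Counter

from fruitfba import (
    build_reference_model,
    classify_genes,
    classify_model_reactions,
    scenario_contrast,
    weights_from_classes,
)

model = build_reference_model()
contrast = scenario_contrast("MG_E1vsE2", seed=42)

gene_classes = classify_genes(contrast, lfc_threshold=1.0, require_significance=True)
print(f"contrast {contrast.contrast_id}: {len(contrast.records)} genes")
print("gene classes:", dict(Counter(c.value for c in gene_classes.values())))

reaction_classes = classify_model_reactions(model, gene_classes)
print("reaction classes:", dict(Counter(c.value for c in reaction_classes.values())))

weights = weights_from_classes(model, reaction_classes)
down = [rid for rid, (cls, _) in weights.weights.items() if cls.value == "down"]
print(f"down-classified (penalty {weights.scheme['down']}): {sorted(down)}")

# Reactions without gene association (pools, transport, NGAM) are always
# neutral: transcripts carry no evidence about pseudo-reactions.
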