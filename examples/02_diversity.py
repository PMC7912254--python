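"""Alpha- and beta-diversity of a rarefied count table.

Rarefaction standardizes all samples to the shallowest library before
comparing diversity; Chao1 estimates richness, Shannon blends richness and
evenness, Faith PD adds phylogenetic breadth; Bray-Curtis and the UniFrac
pair measure between-sample dissimilarity.
"""

from gutdiet.diversity import alpha_diversity, beta_diversity
from gutdiet.preprocess import rarefy
from gutdiet.simulate import StudyConfig, generate_study

tree, table, *_ = generate_study(StudyConfig(seed=42))
rare = rarefy(table, seed=1)
print(f"rarefied {len(rare.sample_ids)} samples to "
      f"{int(rare.sample_totals().iloc[0])} reads each")

alpha = alpha_diversity(rare, tree)
print("\nalpha diversity (first 3 samples):")
print(alpha.head(3).round(3).to_string())
print("\ncohort means:", alpha.mean().round(2).to_dict())

for metric in ("bray_curtis", "weighted_unifrac", "unweighted_unifrac"):
    dm = beta_diversity(rare, tree, metric)
    print(f"{metric}: mean pairwise distance "
          f"{dm.condensed_form().mean():.3f}")
# Larger mean distances indicate more between-sample community turnover.
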