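"""Species richness and Faith's phylogenetic diversity over colonization time.

Richness counts taxa present in a sample; Faith's PD sums the branch
lengths of the smallest rooted subtree spanning them, so it grows when a
newly arrived taxon is phylogenetically distant from the residents.
"""

from assemblage import DesignConfig, RegimeConfig, generate_study
from assemblage.alpha import alpha_table, alpha_trajectories

design = DesignConfig(n_lakes=2, n_taxa=150, sequencing_depth=1500, seed=7)
table, metadata, tree, _, _ = generate_study(design, RegimeConfig())

alpha = alpha_table(table, tree)
print(alpha.head(3).round(2).to_string(index=False))

traj = alpha_trajectories(alpha, metadata, group_by=["lake", "fraction"])
plast = traj[traj.fraction == "plastisphere"]
print(plast.round(2).to_string(index=False))
# Mean +/- sd per lake and day: the plastisphere trajectory of diversity
# during biofilm succession (sd is blank for single-sample groups).
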