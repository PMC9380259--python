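"""PAFS ranking, kinase activity inference (KSEA) and set statistics.

Joins significant sites to machine-learned functional scores (> 0.6
selects the biologically prioritized sites), infers kinase activities
from substrate fold changes, and relates two sample groupings with the
Szymkiewicz-Simpson overlap coefficient.
"""

from pafskit.enrichment import ksea, overlap_coefficient, pafs_rank, set_ora
from pafskit.phospho_stats import sam_test
from pafskit.simulate import gen_functional_scores, gen_kinase_map, gen_phospho_dataset

table, truth = gen_phospho_dataset(n_sites=1500, scale="log2", seed=31)
diff = sam_test(table)

scores = gen_functional_scores(table.sites, truth, high_score_fraction=0.8, coverage=0.9, seed=31)
ranked = pafs_rank(diff, table.sites, scores, threshold=0.6)
selected = ranked[ranked["selected"]]
print(f"PAFS: {len(selected)} of {int(diff['significant'].sum())} significant sites "
      f"score > 0.6 ({ranked.attrs['n_unscored']} unscored)")
print(selected.head(5).to_string())

kmap = gen_kinase_map(25, 15, table.sites, seed=31)
activities = ksea(diff, table.sites, kmap, min_substrates=3)
print(f"\nKSEA: top kinase {activities['kinase'].iloc[0]} "
      f"z = {activities['z'].iloc[0]:+.2f} (p = {activities['p'].iloc[0]:.3f})")
# z > 0 means the kinase's substrates are up-shifted relative to the
# all-site background: inferred activation by treatment.

universe = set(table.sites["protein"])
pathway = set(list(universe)[:80])
hits = set(table.sites.loc[diff["significant"], "protein"])
ora = set_ora(hits, universe, {"toy_pathway": pathway})
print(f"\nORA: overlap {ora['overlap'].iloc[0]}/{ora['set_size'].iloc[0]}, "
      f"p = {ora['p'].iloc[0]:.3f}, q = {ora['q'].iloc[0]:.3f}")

responders = {"P01", "P02", "P03", "P04"}
flt3_itd = {"P02", "P03", "P09", "P11", "P12"}
print(f"\noverlap coefficient (responders vs FLT3-ITD): "
      f"{overlap_coefficient(responders, flt3_itd):.2f}")
# |A & B| / min(|A|, |B|): 1.0 would mean one grouping is contained in
# the other; small values argue against a genotype-response association.
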