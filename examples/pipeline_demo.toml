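# Desk-scale end-to-end demo: simulate every input, then run all stages.
# Every threshold of the analysis appears exactly once, named.

[run]
out_dir = "pankiwi_demo_out"
seed = 7
stages = ["simulate", "partition", "popgen", "sv", "tree", "rga"]

[simulate]
n_assemblies = 15
n_sites = 4000
n_svs = 1000
fst_target = 0.2

[partition]
softcore_frac = 0.85    # softcore floor: >= 85% of assemblies
focal_group = "LG"

[popgen]
pair = ["LG", "MG"]
merge = { MG = ["MG1", "MG2"] }   # pool the two MG subclades
window = 20000                    # FST window (bp)
step = 20000
hdr_percentile = 95.0             # HDR threshold percentile
thin_gap = 2000                   # SNP thinning distance (bp)

[sv]
window = 100000                   # hotspot scan window (bp)
step = 20000                      # hotspot scan step (bp)
hotspot_percentile = 95.0         # top 5% densest windows
favored_hi = 0.5                  # focal-group frequency must exceed
favored_lo = 0.05                 # every other group must stay below
max_missing = 0.5                 # genotype missing-rate cap
maf = 0.05                        # minor-allele-frequency floor
context_flank = 1000              # upstream/downstream flank (bp)
upstream = 2000                   # hotspot-upstream gene window (bp)

[tree]
distance_mode = "dosage"

[rga]
cluster_max_gap = 200000          # same-family clustering reach (bp)
paired_max_gap = 20000            # paired-NLR intergenic gap cap (bp)
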