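# lotteryassembly

Statistics for detecting **competitive-lottery assembly** in microbial
community abundance tables.

The competitive lottery model, originally developed for reef-fish ecology,
posits a pool of niche-equivalent species of which a single, randomly
determined member captures the entire niche in each local community. Applied
to the gut microbiome, a lottery-governed taxonomic group (say, a genus of
16S OTUs) should show (i) one member holding essentially all of the group's
abundance in each sample and (ii) different members winning in different
samples. This package quantifies both signatures for every taxonomic group
at every rank of a feature-by-sample abundance table, and ships generative
models for validating the procedure on synthetic data.

## The statistics

For a group \(G\) with members \(m\) and within-group relative abundance
\(f_{m,s} = x_{m,s} / \sum_{m' \in G} x_{m',s}\) in sample \(s\):

* a **winner** in sample \(s\) is a member with \(f_{m,s} > 0.9\) (at most
  one exists);
* **winner prevalence** is the fraction of included samples containing a
  winner, where a sample is included when the group's summed abundance
  exceeds 0.5%;
* **winner diversity** is the Shannon entropy (base 2) of winner identities
  across winner-bearing samples, normalized by \(\log_2\) of the number of
  distinct winners, hence in \([0, 1]\).

Groups with prevalence > 0.75 **and** normalized diversity > 0.25 are
classified *lottery-like*; high prevalence with low diversity marks a
*fixed winner*; everything else is *non-lottery*. Higher-rank taxa (family,
order, class, phylum) are scored identically with the aggregated abundances
of their child-rank subgroups as members, and per-subject time series are
scanned for **winner turnover** (two eligible time points with different
winners).

## Worked example

```python
import lotteryassembly as la

# simulate a 4-genus community: two lottery genera, one fixed winner,
# one evenly coexisting genus; 300 noise-free samples
spec = la.build_community_spec(
    ["lottery", "lottery", "fixed_winner", "coexistence"],
    n_members=4, n_samples=300, seed=11)
table, lineages, truth = la.simulate_community(spec)

groups = la.build_groups(lineages, "genus")
results = [la.group_lottery_stats(table, g) for g in groups]
print(la.results_to_frame(results).to_string(index=False))
```

prints

```
 group  rank  n_members  n_samples  winner_prevalence  n_winners  winner_diversity classification
g__G00 genus          4        298                1.0          4          0.999724   lottery_like
g__G01 genus          4        294                1.0          4          0.997883   lottery_like
g__G02 genus          4        291                1.0          1          0.000000   fixed_winner
g__G03 genus          4        295                0.0          0               NaN    non_lottery
```

The two lottery genera have a winner in every included sample
(prevalence 1.0) and near-maximal winner diversity (all four members win at
roughly equal frequency); the fixed-winner genus is always dominated by the
same member (diversity 0); the coexistence genus never produces a winner, so
its diversity is undefined.

## Command line

A thin `lottery` CLI wraps the library:

```bash
lottery filter    --table t.biom --out filtered.tsv          # inclusion filters
lottery metrics   --table t.biom --rank genus --out stats.tsv
lottery hierarchy --table t.biom --out hierarchy.tsv         # family..phylum
lottery turnover  --table t.biom --metadata meta.tsv --out turnover.tsv
lottery simulate  community|noise-sweep|longitudinal|genes ...
lottery compare   --stats a.tsv --stats b.tsv --out rho.tsv  # Spearman
lottery genes     --stats-primary a.tsv --stats-other b.tsv \
                  --genomes genomes.tsv --out genes.tsv
```

Inputs: BIOM 2.x (HDF5) or QIIME-classic TSV tables with GreenGenes-style
lineages, MetaPhlAn merged tables (`--metaphlan`), sample-metadata TSV
(`sample_id`, `subject_id`, `time_point`), and a per-species gene-count TSV
(`species_id`, `genus`, `n_genes_total`, `n_genes_ko`, `n_genes_no_ko`).

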