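# Methods

## Scope and data model

`sectormap` consumes per-sample SNP calls (VCF v4.x with FORMAT/AD allelic
depths), a reference genome (FASTA), gene models (GFF3 CDS features) and an
error-prone-site blacklist (BED or two-column TSV).  Coordinates are 1-based
inclusive internally; BED intervals are converted on read.  Only biallelic
SNPs are modelled — EMS lesions are point mutations — and indel or
multi-allelic records are skipped with a counted warning rather than split.

A variant's `depth` is defined as the sum of its allelic depths (AD ref +
AD alt) and its allele frequency is always recomputed as alt/(ref + alt),
never trusted from an INFO annotation.  This gives the 0.99 homozygosity
threshold a single, caller-independent definition; reads supporting a third
base at the site count toward neither depth.  Calls on chromosomes absent
from the reference are rejected at pipeline entry.

## Pooled-mapping model

In an F2 from a cross of the mutant line to another parent, individuals
selected for the recessive phenotype are homozygous for the causal allele.
A mutant-parent variant at genetic distance *d* Morgans rides on each
selected chromosome with probability 1 − r, r = ½(1 − e^(−2d)) (Haldane map
function, no interference); unlinked variants segregate at expected pool
frequency ½, and fertile siblings carry the causal allele on ⅓ of
chromosomes (⅓ homozygous wild type, ⅔ heterozygous).

The filter chain retains a call if depth ≥ `min_depth` (default 2) and
frequency ≥ `freq_threshold` (default 0.99); removes calls whose exact
(chrom, pos, ref, alt) is also homozygous in the sibling pool under the same
thresholds; removes blacklist positions; and keeps only G→A / C→T changes.
Set operations commute, so the order between sibling subtraction and
blacklist removal is immaterial; each step is non-increasing and the counts
are logged.

Surviving variants are counted in `bin_size` (default 1 Mbp) bins tiling
each chromosome from position 1 (bin of a position is
⌊(pos − 1)/bin_size⌋).  "Background" is the median bin count genome-wide —
robust to the peak itself and zero-inflation.  The mapping interval grows
from the genome-wide maximum bin in both directions until
`consecutive_background` (default 2) successive bins sit at or below
background; bins at/below background inside an unfinished run stay in the
interval, reproducing the visual "return to background" logic of a density
plot.  No interval is called when the peak does not exceed background by
more than `min_peak_excess` (default 3), avoiding intervals on flat noise;
ties between equal peaks resolve to the lower (chromosome order, bin start)
and are logged.  With two pools, the shared variants (exact allele identity,
not position only) inside both single-pool intervals define the refined
interval as their coordinate span.

## Consequence classification

SNP consequences are computed only within CDS: the position is mapped into
the spliced CDS honouring strand (bases and the alternate allele
complemented on −), the containing codon is translated with the standard
nuclear genetic code for reference and alternate, and the change is
classified stop_gained/stop_lost (HIGH), missense (MODERATE), synonymous
(LOW); in-gene non-CDS positions are intron_or_utr and everything else
intergenic (MODIFIER).  Protein changes use single-letter HGVS-style
notation (`p.Q150*`), with `*` for stop.  Overlapping genes are all
annotated and the highest-impact annotation reported (tie → lowest gene id).
Splice-site, start-lost and indel logic are deliberately out of scope; a
full-CDS retranslation oracle in the test suite guarantees exact agreement
on the modelled classes.  Candidate tables keep HIGH/MODERATE rows, HIGH
first, then position.

## Sector analysis

Heterozygous calls require depth ≥ `het_min_depth` (default 10), frequency
inside `freq_window` (default [0.25, 0.75], operationalising "~50%" under
binomial sampling at ~60× while excluding homozygous calls and low-level
somatic noise) and the EMS spectrum.  A sterile-sector call within the
mapped interval is *sterile-unique* when the fertile sector shows alt
fraction ≤ `err_max` (default 0.02) for that alternate allele — absence of
a call, or a call for a different alternate, counts as no evidence.  The
genome-wide unique tally is reported alongside the interval-restricted one.
The prior-allele control requires a call at the known site in both sectors,
each within the frequency window.

Phasing uses only reads observing reference-or-alternate alleles at both
sites of a pair (third-base observations drop the read).  With n informative
reads and tolerance `max_discord_frac` (default 0.05): **cis** when
concordant reads (both-alt + both-ref) are ≥ (1 − 0.05)·n; **trans** when
single-alt reads are, with both orientations represented; **ambiguous**
otherwise or when n < `min_informative` (default 3).  The rule is symmetric
in its sites and is verified against exhaustive enumeration of all
classification multisets up to 12 reads.  A gene is nominated when its
sterile-unique coding variants show at least one definite cis pair and no
trans pair among themselves (an ambiguous pair — no spanning reads — is
absence of evidence, not evidence against cis; a singleton is vacuously
cis), plus at least one trans and no cis verdict against the prior allele.
More than one qualifying gene cancels the nomination with a warning.

## The simulator

`simulate_screen` is deterministic for a given config: one root seed spawns
fixed-order child streams for reference, genes, site placement, the two pool
pairs and the sector pair.  The reference has uniform base composition.  A
causal gene (two CDS exons, plus strand) is planted at the centre of the
middle chromosome with codons 98/111/150 forced to CCA/CAA/CAG, so C→T at
their first bases yields P98S, Q111* and Q150* — 39 bp between the novel
pair and 117 bp from the second novel site to the prior stop site, the
geometry the sector screen must resolve with 150-bp reads.  Two single-exon
decoy genes per chromosome (random strand) exercise strand handling.

EMS lesions are drawn only at G/C positions and are always G→A or C→T.  The
causal parent's background load is planted as an exact count
(`n_background`, default 200) shared by both F2 pool pairs, as two crosses
of the same mutant line; a rate-based generator (per-G/C-site Bernoulli)
backs the spectrum/count properties.  Read sampling draws site depth from
Poisson(`mean_depth`) and applies a symmetric substitution error: a read
reports its true base with probability 1 − e and each other base with e/3;
only ref/alt-supporting reads enter the emitted AD.  Sibling-shared sites
are planted homozygous in both pools; blacklist sites homozygous in all
samples.  Sector reads over the gene neighbourhood (±1 kb) are assigned a
haplotype (0 carries the prior allele, 1 the novel pair in the sterile
sector only) and record per-read alleles at covered variant sites; sector
VCF calls inside the region are derived from those same reads, and
heterozygous background sites outside it are sampled binomially at
`sector_mean_depth` (default 60).  Second-parent background variants are
off by default and configurable.

Default study conditions (a deliberately scaled-down screen): 5 chromosomes
× 10 Mbp, pools of 40 mutant + 40 sibling individuals at 12× with 1% error,
0.5 Morgans/Mbp, 200 background EMS variants, 50 sibling-shared and 50
blacklist sites; sector sequencing at 60× with 150-bp reads, 40 shared and
20 sector-unique heterozygous background variants.  Sector-scale runs in
the acceptance measurements use a single 2-Mbp chromosome — the sector
computation only depends on the mapped region and its read neighbourhood —
with a 2-Mbp candidate interval centred on the gene.

What the simulator does *not* emulate: real read alignment (observations
are an explicit site × read table; mapping artefacts, indels and coverage
biases are absent), linkage disequilibrium structure beyond a uniform
Haldane map, multi-generation pedigrees, homozygous somatic events in
sectors, and chromosomal aberrations.  Passing tests therefore demonstrate
the correctness and calibration of the *computation*, not robustness to
alignment pathologies in real data.

## Behaviour at the default study conditions

Two regimes are worth distinguishing, both measured by the test suite and
`scripts/acceptance.py`.  Under a moderate genetic map (e.g. 0.05
Morgans/Mbp at 30×, the worked example in the README), the pipeline
recovers the interval and the causal stop-gain essentially always.  Under
the hot default map (0.5 Morgans/Mbp at 12×), the probability that a linked
variant x Mbp from the causal site survives the all-reads-alternate 0.99
filter falls as ~e^(−6x), so the expected retained cluster is only ~2–3
variants; that sits below the peak-prominence rule (median + 3), and
interval detection then correctly declines to call a region — recovery
rates at those settings are low and the acceptance report says so.
Similarly, with 1% sequencing error a planted sibling-shared site leaks
past the subtraction when a single alt→ref error read drops the sibling
call below 0.99 (~4% per site at 12×), and a fertile-sector error read can
push a novel site's fertile alt fraction above the 0.02 floor (~3% per
site at 60×), so removal and sector-recovery rates below 100% at these
settings reflect the thresholds' sampling behaviour, not implementation
error — the blacklist and spectrum filters, which are positional and
deterministic, are exact in every run.

## Numerical and design choices

* Background = median (not mean) bin count: insensitive to the peak and to
  a handful of noisy bins.
* Exact allele identity in pool intersection: stricter than positional
  matching and correct for biallelic EMS sites.
* `err_max` compares alt fraction, not call presence: robust to caller
  sensitivity differences between sectors.
* All thresholds live in one validated `PipelineParams` bundle; unknown
  keys and out-of-range values are rejected before any computation.
* Degenerate inputs: empty pools yield empty filtered sets and all-zero
  bins; an all-background genome yields no interval; phasing a site against
  itself, a missing prior-site call, and intervals on different chromosomes
  raise informative errors.
* Seeds: a config's single seed determines every byte of simulator output;
  `scripts/acceptance.py` derives independent sub-seeds (< 2³¹) from its
  `--seed` via `SeedSequence`.
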