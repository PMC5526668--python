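# rescuemap

Analysis toolkit for evolutionary-rescue experiments that probe how the
chromosomal neighborhood of a gene under selection shapes adaptation. The
package covers the full computational pipeline:

- **Trajectory classification** — OD600-normalized YFP/CFP plate-reader time
  series; rescue calls (final OD above threshold), fluorescence phenotype
  calls (fold increase over an ancestral reference above 2.77), stringent
  transient-amplification criteria, final YFP/CFP ratios, and a
  ratio-trajectory rule for ordering amplifications relative to co-occurring
  mutations.
- **Selection design** — MIC determination on a discrete concentration grid
  (lowest concentration with OD ≤ 0.075 in all replicates), geometric drug
  schedules (half-MIC start, 10-fold increase by day 10), and the generation
  count implied by daily 1:820 serial dilution (~97 over 10 days).
- **qPCR copy number** — efficiency-corrected ddCq quantification against a
  reference locus and an ancestral calibrator, with delta-method SD
  propagation and the copy-number/CFP correlation check.
- **Neighborhood map** — direct-repeat detection (length ≥ 200 bp, Hamming
  distance ≤ 8, gap between 200 bp and 100 kb; exact k-mer seeding with a
  pigeonhole-sound seed length plus maximal ungapped extension), strand-aware
  upstream scans for the closest co-oriented terminator (Rho-dependent
  read-through set), deletion-based promoter co-option constrained by
  essential genes, genes between flanking duplicates, and the combined
  three-set adaptive-potential tier per gene.
- **Statistics** — exact r×c Fisher tests (probability-mass two-sided
  criterion, full enumeration with a Monte Carlo fallback), 2×2 sample odds
  ratios with explicit zero-cell semantics, seeded two-sample permutation
  tests (exact enumeration for small n, add-one-corrected Monte Carlo
  otherwise), and Pearson correlation.
- **Simulator** — a stochastic serial-transfer rescue simulator (bacteriostatic
  threshold growth model, copy-number random walk for amplified lineages,
  per-copy amplification cost scaled by amplicon length, scenario presets for
  the six strain neighborhoods) that emits plate CSVs with per-well ground
  truth, plus a toy-genome generator with planted repeats, promoters,
  terminators and essential genes whose set memberships are known by
  construction. All simulator defaults are synthetic, calibrated only to
  reproduce qualitative regimes — never exact experimental counts.

## CLI

A single entry point with one subcommand per analysis stage:

```sh
rescuemap simulate --preset B --n-wells 95 --seed 1 --out plates.csv --truth truth.csv
rescuemap classify-trajectories --plates plates.csv --ancestor anc.csv --out calls.csv
rescuemap mic --od od.csv --concentrations 0.25,0.5,0.75,1.0
rescuemap schedule --mic 1.0 --days 10 --out schedule.csv
rescuemap qpcr --in cq.csv --calibrator ANC --out copies.csv
rescuemap repeats --fasta genome.fa --out repeats.bed
rescuemap neighborhood --fasta genome.fa --annotation ann.gff3 --out map.tsv --venn-out venn.json
rescuemap stats fisher --table counts.csv
rescuemap stats permtest --x x.txt --y y.txt --reps 10000 --seed 1
rescuemap make-fixtures --kind annotation --seed 2 --out toy/
rescuemap demo --seed 7 --out demo_out
```

Every stochastic command takes an explicit `--seed`; reruns with the same
seed are byte-identical.

## File conventions

Internal coordinates are 0-based half-open everywhere; GFF3 I/O is 1-based
closed; BED is 0-based half-open. Plate data are tidy CSV
(`plate_id, well, day, od600, yfp, cfp`; days 1-based and contiguous), with a
wide-to-long converter for plate-shaped sheets. qPCR tables are long CSV
(`sample, assay, cq, efficiency`), one row per technical replicate.

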