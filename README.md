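# tsppi

Analysis toolkit for identifying and characterising **tumour-specific
protein–protein interactions (TSPPIs)** — complexes present in tumour cells
but absent from reference tissue — and for dissecting the downstream
genomic co-dependency of the two partners. The package re-implements, as a
tested and reusable pipeline, the analysis arms of a TNBC study design built
around a BCL11A-type bait and its tumour-specific partner:

1. **Differential IP–MS interactome comparison** — per-run IgG-control
   subtraction, a unique-peptide floor, cumulative Mascot-score weights, and
   cross-group set algebra. The candidate rule nominates proteins found in
   *every* tumour run and *no* reference run.
2. **ChIP-seq consensus-peak co-dependency** — peaks from all samples are
   merged when the midpoint of one falls within the span of another;
   amplitudes are summed coverage scaled on read length; a signal/noise floor
   of 20 is applied; samples are aligned on the mode of their log2 amplitude
   distribution against the matching control IP; "disappearing" peaks
   (log2(control/knockdown) ≥ 0.5) under each knockdown are combined into an
   A-specific / B-specific / shared (co-dependent) / unchanged partition.
3. **6-mer motif enrichment** — per-sequence presence of canonical
   (strand-collapsed) 6-mers in disappearing-peak sequences, one-sided
   Fisher exact tests against two backgrounds (all peaks; gene upstream
   regions), with Benjamini–Hochberg values reported alongside.
4. **RNA-seq overlap integration** — quadrant classification of two
   knockdown DE tables (co-down / co-up / discordant), an OLS trend fit of
   the shared effects, intersection of shared DE genes with genes near
   co-dependent peaks, and ΔΔCt quantification of qPCR tables
   (fold change = 2^(−ΔΔCt)).
5. **SPR steady-state affinity** — double referencing (reference flow cell
   and zero-concentration blank subtraction), equilibrium responses read at
   the end of the association phase, and nonlinear least-squares fitting of
   the 1:1 Langmuir isotherm

   ```
   Req(C) = Rmax · C / (KD + C)
   ```

   plus percent-inhibition scoring of fragment competition experiments,
   100·(1 − R_with/R_alone).

Everything runs on a **seeded synthetic-data generator**
(`tsppi.synthetic_data`) that emulates each input format with planted
ground truth: peak co-dependency classes, correlated shared DE effects, a
protein present in all group-A runs only, a planted GC-rich 6-mer, and 1:1
binding kinetics with drift/bulk artefacts and noise. The generator is
first-class, tested code; its truth files drive the recovery test suite.

## Worked example

```
tsppi run-all --seed 1 --out demo_out
```

simulates a complete dataset (2 × 1 Mb genome, 200 genes, 560 binding loci,
two DE tables, 9 IP–MS runs, a 9-cycle SPR series) and chains every stage.
The printed report (abridged):

```json
{
 "interactome": {"candidates": ["CANDID01"], "a_union": 81, "b_union": 34,
                 "shared": 20, "a_only": 61},
 "peaks": {"n_consensus": 560,
           "class_counts": {"A_specific": 100, "B_specific": 60,
                            "shared": 100, "unchanged": 300}},
 "atac": {"mean_log2fc_codependent_promoters":
          {"atac_kdA": 0.0002, "atac_kdB": 0.78}},
 "motifs": {"top_motif": "GCCGCC", "n_tested": 2080},
 "integrate": {"quadrants": {"co_down": 130, "co_up": 237, "discordant": 1,
                             "a_only": 256, "b_only": 452, "shared": 368},
               "r_squared": 0.88, "n_intersection": 78,
               "intersection_directions": {"up": 40, "down": 38}},
 "spr": {"kd_nM": 868.4, "rmax_RU": 249.4, "converged": true}
}
```

Reading the numbers: the planted interactor `CANDID01` is the unique
protein found in all seven group-A runs and no group-B run; all 560 planted
binding loci are recovered with their exact co-dependency classes; ATAC
accessibility at co-dependent promoters drops only under the B knockdown;
the planted GC-rich motif `GCCGCC` is the top enrichment among 2080 tested
6-mers; the DE overlap decomposes into 237 + 130 + 1 = 368 shared genes
whose effects correlate at R² ≈ 0.9, 78 of which (38 down, 40 up) also sit
next to co-dependent peaks; and the steady-state fit recovers the generator's
true affinity of 870 nM.

Individual stages are available as `tsppi simulate|interactome|peaks|atac|
motifs|integrate|ddct|spr` subcommands, and every operation is importable
directly (`tsppi.peak_analysis.build_consensus`, ...).

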