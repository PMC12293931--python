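# crossfam

Cross-reactivity analysis of CRISPR/Cas9 editing within gene families from
long-read amplicon sequencing.

## The problem

Gene families arise by duplication, so paralogs retain high sequence
similarity — and a guide RNA designed against one family member is at risk of
cutting its siblings.  Short reads often cannot be assigned unambiguously
among near-identical paralogs; long (CCS-style) reads covering a full ~1 kb
amplicon can.  `crossfam` is a toolkit for scientists who have amplified and
long-read-sequenced the members of a gene family after CRISPR treatment and
want to know, per member and per putative recognition site, how much on- and
off-target editing occurred.

## The method

For a family with amplicons F1..Fn and designed guides g1..gn (one per
member), `crossfam`:

1. **Enumerates candidate off-target sites.**  For every ordered pair
   (i, j), j ≠ i, it collects all 20-bp windows adjacent to a PAM
   (default NGG) on either strand of Fj, and keeps those with pairwise
   alignment score ≥ *S* and Levenshtein edit distance ≤ *D* against gi.
   The result is the candidate list L(i, j), with counts
   k(i, j) = |L(i, j)| and k_i = max_j k(i, j).
2. **Builds per-target configuration tables** pairing each amplicon with
   either its designed guide (on-target row) or a putative recognition
   sequence from L(i, j) (off-target rows) — the hand-off format for
   per-site quantification, here or in an external amplicon analyzer.
3. **Quantifies activity from reads.**  Reads are assigned to amplicons by
   whole-read edit distance, aligned to their reference, and called *edited*
   at a site when the alignment contains an indel overlapping a ±10 nt
   window around the predicted blunt cut (3 nt 5′ of the PAM).  Each
   (site, sample) gets an edited-read proportion p̂ with a Wilson 0.95
   interval, a one-sided Fisher exact comparison against the mock
   (no-nuclease) control, and — whenever a mock is present — a
   background-corrected activity (p̂_t − p̂_m)/(1 − p̂_m) with a
   Newcombe-style 0.95 interval, which is unbiased for the true edited
   fraction when indel sequencing errors land in the window at the same
   rate in both arms.
4. **Simulates ground truth.**  A synthetic-data module generates paralog
   families (shared ancestor, configurable divergence), plants on-target
   sites and off-target 20-mers at an exact edit distance, and emits
   CCS-like reads with configurable error and editing rates — so every
   stage is testable against known answers.

## Worked example

Simulate a two-member family (~1 kb, 5% divergence) with a cross-reactive
site planted in S2 at edit distance 6 from guide S1, strong on-target editing
(60%) and weak off-target editing (5%), three treated replicates plus a mock;
then run the analysis:

```bash
crossfam simulate --members 2 --length 1000 --divergence 0.05 \
    --plant S1:S2:6 --reads 2000 --replicates 3 --mock \
    --edit-rate S1_on=0.6 --edit-rate S2_off1_S1=0.05 --seed 7 --outdir sim
crossfam enumerate --fasta sim/amplicons.fasta --guides sim/guides.csv \
    --pam NGG --min-score 10 --max-ed 12 --per-pair-limit 2 --out sites.csv
crossfam config --fasta sim/amplicons.fasta --guides sim/guides.csv \
    --sites sites.csv --target S1 --out configS1.csv
crossfam quantify --config configS1.csv --samples sim/samples.csv \
    --window 10 --out activity.csv
crossfam report --activity activity.csv --config configS1.csv --out report.csv
```

`sites.csv` starts with the selected sites for guide S1 in sibling S2 —
the planted site is recovered as α at its true edit distance:

```
target_guide,host_amplicon,position,strand,protospacer,pam,alignment_score,edit_distance,is_on_target,label
S1,S2,742,-,ATGCTTTACTGGCGGACGCC,GGG,16,6,False,α
S1,S2,741,-,TGCTTTACTGGCGGACGCCG,GGG,15,8,False,β
```

and `report.csv` contains (abridged):

```
site_name sample  n_reads  n_edited   rate  corrected_rate  significant_vs_mock
    S1_on   rep1     2000      1317 0.6585        0.604745                 True
    S1_on   mock     2000       272 0.1360             NaN                False
     S2_α   rep1     2000       318 0.1590        0.037207                 True
     S2_α   mock     2000       253 0.1265             NaN                False
```

Reading this: the raw edited proportion includes a ~13% background of indel
sequencing errors falling inside the call window (visible directly in the
mock rows).  The mock-corrected activity recovers the planted truth — ~60%
at the on-target site and ~4–6% at the α site (truth 5%) — and both are
significant against the mock.  Site β overlaps α's window by 19 bases, so it
reports the same editing events.  The `report.csv` display column shows
sub-floor values as `*` (0.3% floor for on-target views, 0.01% for
off-target views), and `crossfam report --plot` draws the per-site bars with
0.95 CIs and dashed 0.1%/1% reference lines.

The whole pipeline also runs from one YAML document
(`crossfam run --config run.yaml`), writing sites, configs, activity,
reports and a manifest into an output directory; reruns with the same
configuration and seed are byte-identical.

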