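# sicall

Differential pre-mRNA splicing analysis from splice-junction reads, for
regulator perturbation studies — the setting where a candidate splicing
regulator (here modelled on the RNA-editing enzymes ADAR1/ADAR2) is both
knocked down and overexpressed against matched controls, and an event is
trusted only when its splicing moves in **opposite directions** under the
two perturbations.

`sicall` is a library plus CLI for:

* enumerating candidate alternative-splicing events (cassette exons,
  intron retention, alternative 5′/3′ splice sites) from a GTF;
* extracting and counting splice junctions from SAM alignments (CIGAR
  `N` operations) or STAR `SJ.out.tab` tables, with reads classified
  into exon–exon junction, exon–intron bridging, and fully intronic
  groups;
* quantifying each event's **splicing index** per sample;
* calling differential events per contrast (Fisher exact test + BH-FDR)
  and joining knockdown/overexpression contrasts with the bidirectional
  consistency filter;
* building motif-analysis inputs (event ± 250 nt flanks) and scanning
  for GA-rich elements;
* AS-NMD logic: reading-frame projection of an exon skip, premature
  termination codon (PTC) location, and the 50-nt rule;
* small clinical/assay rules (tumor-pair classification, RIP %input,
  xenograft tumor volume);
* a fully deterministic synthetic-data generator with known truth, so
  the whole cascade is testable end to end without any external data.

## The statistic

For an event with inclusion-supporting junction reads $I$ and
skipping-supporting reads $S$ in one sample, the splicing index is

$$\mathrm{SI} = \frac{I}{I + S},$$

an estimate of percent-spliced-in (PSI) from junction evidence. How raw
junction counts map to $I$ and $S$ is adjusted per event type: a
cassette exon averages its two flanking inclusion junctions against the
exon-skipping junction; an alternative splice site compares the
longer-exon junction against the alternative one; intron retention
compares exon–intron bridging reads against the spliced junction (with
intronic coverage and depth as a QC gate).

Per contrast, pooled counts form a 2×2 table
$[[I_t, S_t], [I_c, S_c]]$ tested with a two-sided Fisher exact test;
p-values are Benjamini–Hochberg adjusted across all events of the
contrast. An event passes the screen when

* total junction reads ≥ 15 (in each arm),
* |ΔSI| = |SI_t − SI_c| ≥ 0.10, and
* FDR-adjusted p < 0.2,

and becomes a **high-confidence call** when the ΔSI signs are opposite
between knockdown and overexpression — in every contrast (`strict`) or
in at least one KD/OE pair (`relaxed`).

## Worked example

Simulate a 200-gene study (20 cassette exons shifted by |ΔPSI| = 0.3,
opposite directions between KD and OE; two regulators, each with a
two-replicate knockdown arm and a one-replicate overexpression arm) and
run the full screen:

```python
from sicall.simulate import SimConfig, generate
from sicall.pipeline import run_pipeline

cfg = SimConfig(seed=42, n_genes=200, n_events_shifted=20)
out = generate(cfg, "demo_sim")
config = {
    "annotation": str(out.gtf),
    "samples": {s: {"sj": str(out.sj_dir / f"{s}.SJ.out.tab")}
                for s, _ in cfg.samples},
    "contrasts": [
        {"id": cid, "kind": "KD" if t.endswith("-KD") else "OE",
         "treatment": [s for s, c in cfg.samples if c == t],
         "control": [s for s, c in cfg.samples if c == ctl]}
        for cid, t, ctl in cfg.contrasts
    ],
    "mode": "strict",
}
manifest = run_pipeline(config, "demo_run")
```

The run prints one structured line per stage and writes plain-text TSVs
plus a manifest. For this seed the stage counts are:

```
annotate:  400 transcripts -> 2411 candidate events
diff.ADAR1-KD-vs-ctrl: 2411 tested, 62 passing
diff.ADAR1-OE-vs-ctrl: 2411 tested, 64 passing
diff.ADAR2-KD-vs-ctrl: 2411 tested, 65 passing
diff.ADAR2-OE-vs-ctrl: 2411 tested, 61 passing
join (strict):         55 high-confidence calls
```

Those 55 calls recover 19 of the 20 planted cassette events, and **all
55 lie inside the 20 shifted genes**: the extras are sibling candidates
(alternative framings of the same exon, neighbouring alt-ss events
sharing a shifted junction) that genuinely co-move with the planted
shift. No call lands in any of the 180 null genes. The first call in
`demo_run/high_confidence_calls.tsv`:

```
event_id                           kd_delta_si                    oe_delta_si
A3:simchr1:+:201048-201707|202527  ADAR1-KD=-0.276; ADAR2-KD=-0.289  ADAR1-OE=+0.375; ADAR2-OE=+0.350
```

— splicing down under both knockdowns, up under both overexpressions:
exactly the bidirectional signature the screen is built to find.

The same pipeline runs from the shell: `sicall simulate`, `sicall run
--design design.yaml --out outdir`, plus `sicall nmd`, `sicall motif`
and `sicall classify` for the downstream rules (see `sicall --help`).

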