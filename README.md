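# fragribo

Quantification of endonucleolytic 3' mRNA fragments and stalled-ribosome
footprints, for transcriptome-scale studies of RNase L activation.

When RNase L is activated by 2–5A it cleaves mRNAs after U-N dinucleotides
(UN^N), producing poly(A)-bearing 3' fragments. Two sequencing assays see
the aftermath:

* **Direct RNA nanopore sequencing** of poly(A)-selected RNA captures the
  3' fragments. A read is called a fragment when its aligned span is
  strictly shorter than one third of its annotated transcript, 3'-anchored,
  and between 50 nt and 10 kb. Because the pore cannot sequence the final
  ~10–15 nt of each molecule's 5' end, the cleavage dinucleotide is read
  from the *reference* sequence upstream of the mapped 5' end, where its
  Shannon information content, `IC_j = 2 + Σ_b f_{jb} log₂ f_{jb}` bits,
  peaks at offsets −12/−11.
* **Ribosome profiling with 15–34 nt size selection** captures ribosomes
  stalled at cleaved 3' ends as short 15–18 nt footprints ("16-mers",
  3' end exactly at the cut) alongside elongating 25–34 nt footprints
  ("28-mers"). The 16-mer/28-mer ratio, 3'UTR:CDS rpm ratios (P site =
  5' end + 12 nt), stop-codon and 3'UTR-altORF metagenes, UU-anchored
  3'-end averages, poly(A)-terminated unmapped reads, and fixed spike-in
  oligos quantify the stalling and its controls.

The package also ships a ground-truth simulator that generates
transcriptomes, UN^N cleavage events, pore-truncated nanopore reads, and
footprint mixtures, so every statistic can be validated against known
parameters without downloading data.

## Worked example

Simulate an activated-cell nanopore library (20 000 molecules, 80% cleaved
with weights UU .4 / UA .3 / UG .2 / UC .1, pore truncation mode 10 nt) and
recover the cleavage signature:

```python
import numpy as np
from fragribo import (SimConfig, generate_transcriptome, simulate_cleavage,
                      simulate_nanopore_reads, analyze_fragments, Alignment)

cfg = SimConfig(seed=11, n_reads=20_000)
model = generate_transcriptome(cfg)
rng = np.random.default_rng(cfg.seed)
molecules = simulate_cleavage(model, cfg, rng)
sim = simulate_nanopore_reads(molecules, model, cfg, rng)

alns = [Alignment(r["read_id"], r["transcript_id"], r["ref_start"],
                  r["ref_end"], r["read_len"], bool(r["mapped"]))
        for r in sim.truth_alignments.to_dict("records")]
res = analyze_fragments(alns, model)

print(f"mapped reads          : {len(alns)}")
print(f"3' fragment calls     : {res.n_fragments}")
print(f"motif windows         : {res.n_windows}")
print(f"IC peak offset        : {res.motif.ic_bits.idxmax()}"
      f"  ({res.motif.ic_bits.max():.3f} bits)")
print("U-N second-base spectrum:",
      {k: round(v, 3) for k, v in res.dinucleotides["u_first"].items()})
```

This prints:

```text
mapped reads          : 20000
3' fragment calls     : 4691
motif windows         : 4691
IC peak offset        : -12  (0.449 bits)
U-N second-base spectrum: {'UU': 0.429, 'UA': 0.271, 'UG': 0.188, 'UC': 0.113}
```

Of 20 000 reads, 4 691 pass the strict fragment rule (most cleavage sites
fall outside the last third of their transcript, and intact and background
reads are rejected). The upstream information content peaks at offset −12 —
the first base of the cut dinucleotide displaced by the ~10 nt pore
truncation plus the two motif bases — and the second-base spectrum among
U-first windows recovers the simulated cleavage preference. The remaining
gap to the exact weights is the truncation mixture (only the mode lands the
motif exactly at −12/−11) plus background fragments, both part of the
simulated conditions.

The same objects drive the command line:

```sh
fragribo --seed 11 --out-dir sim simulate-nanopore
fragribo --out-dir out analyze-fragments \
    --alignments sim/nanopore_alignments.tsv \
    --transcriptome sim/transcriptome.fa --annotation sim/annotation.tsv
```

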