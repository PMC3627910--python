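# fanzorkit

A structural-annotation toolkit for the transposable elements that carry
TnpB-like proteins (Fanzor1/Fanzor2) and for the *Helitron2* group of
rolling-circle transposons. It is aimed at repeat curators and mobile-DNA
researchers who need to re-apply, on their own sequences, the detection and
annotation rules that define these element groups:

* **Protein motif scanning** — TnpB and Fanzor proteins share a constellation
  of strictly conserved residues in their C-terminal half,

  ```
  D - X(125,275) - [TS] - [TS] - X - X - [C4 zinc finger] - X(5,50) - RD
  ```

  where `X(a,b)` is a bounded run of unconstrained residues and the C4 zinc
  finger is a four-cysteine ribbon (OrfB_Zn_ribbon). `fanzorkit.motif` finds
  every placement of this signature with configurable spacing bounds.
* **Terminal structures** — terminal inverted repeats (TIRs), stem-loop
  hairpins, and the asymmetric terminal inverted repeat (ATIR) pairs
  diagnostic of *Helitron2*: a 5′-ATIR 0–2 bp from the 5′ terminus pairing
  downstream into a 5′ hairpin, and a subterminal 3′-ATIR immediately
  upstream of the 3′ hairpin. `fanzorkit.terminal` detects all three and
  classifies candidates as *Helitron1* (5′-TC…CTRR-3′, single 3′ hairpin) or
  *Helitron2* (5′-T, ATIR pair, hairpins at both ends).
* **Insertion analysis** — variable-length target site duplications (TSDs,
  typically ~7–19 bp, occasionally hundreds of bp), T-rich target
  tetranucleotide preference (≥3 of 4 bases T: TTTT, TTTG, TTTC, TCTT,
  TGTT, …), empty-site reconstruction, and family-level truncation profiles
  (the 3′-overabundance signature of one-ended replication).
* **Consensus and identity** — end-gap-free affine global alignment, percent
  identity over the aligned span, and majority-rule consensus building.
* **Simulation** — genomes with planted element families (structures, TSDs,
  target preference, geometric 5′ truncation, substitution divergence) plus a
  ground-truth table, used to validate every detector end to end.

## Worked example

Simulate a genome with a TIR family whose copies are flanked by variable
TSDs, then call the TSDs back:

```bash
cat > sim.cfg <<EOF
genome_len = 60000
family1.id = tirfam
family1.element_len = 300
family1.structure = tir:33
family1.copies = 8
family1.tsd = uniform:7:19
EOF
fanzorkit simulate --config sim.cfg --seed 7 --out-prefix sim
# -> wrote sim.fasta with 8 planted copies
fanzorkit call-tsd --loci sim.loci.tsv --flank-fasta sim.flanks.fasta --out calls.tsv
head -3 calls.tsv
```

```
locus_id	status	tsd_seq	tsd_len	left_slack	right_slack	target_tetranucleotide	t_rich
tirfam_c5	tsd	ATCTATAC	8	0	0	ACTT	False
tirfam_c0	tsd	CGTAGCCCAGA	11	0	0	GATT	False
```

Each row is one insertion locus: the duplicated target string found in both
flanks, its length, the boundary slack consumed on each side (0 = the
duplication abuts the annotated element boundary exactly), and the
tetranucleotide immediately 5′ of the duplication with its T-richness flag.
At zero divergence every planted TSD is recovered at its exact length.

The same library surface is available from Python:

```python
from fanzorkit.terminal import classify_helitron
from fanzorkit.simulate import FamilySpec, Helitron2Structure, make_element

elem = make_element(FamilySpec("demo", element_len=400, structure=Helitron2Structure()), 3)
call = classify_helitron(elem)
print(call.verdict)          # helitron2
print(call.atir.ir.arm_len)  # 10
```

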