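# junctioneer

Rearrangement-junction forensics for duplicated plant loci.

Tandemly duplicated genes — like the maize *p1*/*p2* pair, whose alleles
differ in pericarp and cob pigmentation — accumulate a characteristic
repertoire of structural changes: transposable-element (TE) insertions that
leave target-site duplications (TSDs), abortive excisions whose
double-strand breaks are resected and rejoined by non-homologous end-joining
(NHEJ) with short *filler DNA* copied from near the break, unequal crossover
at short exact anchors that expands or contracts the array, and displaced
3' UTRs that recruit new polyadenylation sites from flanking retroelements.
Reconstructing this history from finished allele sequences is a forensic
exercise: every mechanism leaves a diagnostic junction signature.

`junctioneer` implements that exercise as a reusable pipeline for
researchers comparing finished (Sanger-scale) allele or haplotype sequences
of a locus:

* **pairwise comparison** — exact affine-gap global alignment
  (match +1, mismatch −2, gap `4 + k`) up to 20 kb, anchored 15-mer chaining
  with per-region exact DP beyond; SNP / indel-event / identity catalogs
  over all alignment columns ("consensus length" semantics), divergence
  points, and recombination breakpoint intervals bracketed by informative
  sites in a parent–parent–recombinant trio;
* **junction forensics** — junction calling with canonical maximal-flank
  boundary placement, TSD detection (maximal exact direct repeat abutting an
  element), greedy maximal-prefix filler decomposition against donor windows
  on either side of the break (both strands), tandem-array detection with
  exact period and crossover-anchor recovery, flanking-repeat detection, and
  a deterministic precedence classifier
  (`te_insertion` → `tandem_duplication` → `nhej_filler` → `uxo_deletion`);
* **poly(A) mapping** — 3' RACE tail trimming, strict no-indel read
  assignment, maximal templated 3' extension over genomic A-runs, per-site
  count/fraction tables (positions 1-based after the stop codon) with
  min-count reporting and feature-overlap (LTR/TE) summaries;
* **forward simulation** — a seeded generator of tandem-array loci and all
  of the above events with a machine-readable truth log whose replay
  reproduces every derived allele byte-for-byte, so each detector is
  testable without any external data.

## Worked example

Reconstruct an NHEJ deletion scar inside a two-copy tandem array (element
excision, resection of almost a full 1.5-kb unit, repair with a 9-bp filler
copied from 27 bp downstream of the break):

```python
from junctioneer import fixtures
from junctioneer.pipeline import analyze_pair

fix = fixtures.nhej_scar_in_array(seed=1)
alignment, catalog, events = analyze_pair(fix.ref, fix.alt)
event = events[0]
frag = event.filler.fragments[0]
print(event.kind, event.confidence)
print("deletion bp:", event.junction.del_len)
print("filler:", frag.frag_seq, frag.frag_len, "bp from",
      frag.donor_offset, "bp", frag.donor_side)
print("flanking repeats:", event.flanking_repeat.repeat_seq_len, "bp")
```

prints

```
nhej_filler strong
deletion bp: 1297
filler: AACCTATGT 9 bp from 27 bp downstream
flanking repeats: 203 bp
```

— one junction, classified as an NHEJ scar: the 9-bp insertion is fully
explained by a single filler fragment whose donor lies 27 bp downstream of
the deletion endpoint, and because the deletion removed 203 bp less than a
full array unit, the scar is bracketed by exact 203-bp direct repeats.

The same stages are exposed on the command line:

```bash
junctioneer compare ref.fasta alt.fasta --stdout
junctioneer junctions --ref ref.fasta --alt alt.fasta --te-lib te.fasta
junctioneer breakpoint --recombinant R.fasta --parents A.fasta B.fasta
junctioneer polya --reads race.fasta --ref utr.fasta --stop-pos 121
junctioneer simulate --seed 7 --out-dir sim/
junctioneer report --ref sim/ancestor.fasta --alt sim/derived.fasta --out-dir out/
```

Accession-based comparisons (the deposited GenBank records of the *p*
locus alleles) need a one-time download via
`scripts/fetch_accessions.py`; the library itself never touches the
network.

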