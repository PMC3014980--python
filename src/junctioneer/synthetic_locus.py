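"""Forward simulation of tandem-array evolution with a machine-readable
truth log.

The generator emulates the mutational history of a tandemly duplicated
plant locus: an array of near-identical gene copies (period in the kb
range), transposable-element insertions creating 2-12 bp target-site
duplications, abortive excisions causing double-strand breaks whose ends
are resected (geometric lengths) and rejoined by non-homologous end-joining
with 1-2 filler fragments copied from within ~100 bp of the break ends
(either strand), unequal crossover at short exact anchors producing tandem
duplications or deletions of whole or partial units, background SNP/indel
divergence, and 3' RACE reads drawn from a multinomial cleavage-site
distribution with untemplated poly(A) tails.

Every applied event is logged as an :class:`EventRecord`; replaying the
ordered records on the ancestral sequence reproduces the derived allele
byte-for-byte, which is what the detector round-trip tests rely on.
A single :class:`numpy.random.Generator` keyed by the config seed drives
all randomness, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .locus_io import Feature, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    array_copies: int = 11
    period: int = 12_000
    snp_rate: float = 0.01          # per-bp per-copy divergence
    indel_rate: float = 0.001
    tsd_len_range: tuple = (2, 12)
    resection_mean: float = 300.0   # geometric mean resection per break end
    filler_frag_count: int = 2      # 1 or 2 fragments per NHEJ junction
    filler_len_range: tuple = (4, 15)
    filler_window: int = 100
    uxo_anchor_len: int = 8
    flank_len: int = 2_000
    race_site_distribution: Optional[dict] = None   # pos_after_stop -> prob
    n_reads: int = 500
    tail_len_range: tuple = (10, 30)

    def __post_init__(self) -> None:
        if self.array_copies < 1 or self.period < 1:
            raise ValueError("array_copies and period must be positive")
        for lo, hi in (self.tsd_len_range, self.filler_len_range,
                       self.tail_len_range):
            if lo > hi:
                raise ValueError("ranges must be non-empty")
        if not (0 <= self.snp_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must be probabilities")
        if self.filler_frag_count not in (0, 1, 2):
            raise ValueError("filler_frag_count must be 0, 1 or 2")


@dataclass(frozen=True)
class EventRecord:
    event_kind: str
    generation_order: int
    payload: dict


@dataclass
class EventTruthLog:
    config: SimConfig
    records: list = field(default_factory=list)
    derived_allele_ids: list = field(default_factory=list)

    def add(self, kind: str, **payload) -> EventRecord:
        rec = EventRecord(kind, len(self.records), payload)
        self.records.append(rec)
        return rec

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "records": [asdict(r) for r in self.records],
                "derived_allele_ids": self.derived_allele_ids,
            },
            indent=2, sort_keys=True, default=_jsonable,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventTruthLog":
        data = json.loads(text)
        cfg = data["config"]
        for key in ("tsd_len_range", "filler_len_range", "tail_len_range"):
            cfg[key] = tuple(cfg[key])
        log = cls(config=SimConfig(**cfg),
                  derived_allele_ids=data["derived_allele_ids"])
        for r in data["records"]:
            log.records.append(
                EventRecord(r["event_kind"], r["generation_order"], r["payload"])
            )
        return log


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate_snps(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-bp rate (never to the same base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def build_ancestor(config: SimConfig,
                   rng: Optional[np.random.Generator] = None):
    """A tandem array of near-identical unit copies with annotated features.

    Returns (SequenceRecord, features, unit): ``array_copies`` copies of a
    random unit of length ``period``, each copy independently diverged at
    ``snp_rate``, embedded between random flanks.  Three exons and a repeat
    feature are annotated per copy.
    """
    if config.period < 200:
        raise ValueError("period must be >= 200 bp to host gene features")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    unit = random_seq(rng, config.period)
    flank5 = random_seq(rng, config.flank_len)
    flank3 = random_seq(rng, config.flank_len)
    # the first copy is the unit itself; later copies diverge at snp_rate,
    # so a single-copy array carries no inter-copy divergence
    copies = [unit] + [
        mutate_snps(rng, unit, config.snp_rate)
        for _ in range(config.array_copies - 1)
    ]
    seq = flank5 + "".join(copies) + flank3
    record = SequenceRecord("ancestor", seq, "simulated tandem-array locus")
    features = []
    p = config.period
    exon_layout = [(0.05, 0.10), (0.20, 0.24), (0.30, 0.45)]
    for i in range(config.array_copies):
        start = config.flank_len + i * p
        features.append(
            Feature(record.id, "repeat", start, start + p, "+", {"copy": str(i)})
        )
        for k, (lo, hi) in enumerate(exon_layout, 1):
            features.append(
                Feature(record.id, "exon", start + int(lo * p), start + int(hi * p),
                        "+", {"copy": str(i), "exon": str(k)})
            )
    return record, features, unit


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def apply_te_insertion(seq: str, element: str, pos: int, tsd_len: int,
                       log: Optional[EventTruthLog] = None):
    """Insert an element at ``pos`` duplicating ``tsd_len`` target bases.

    The product is seq[:pos+tsd_len] + element + seq[pos:], i.e. the target
    bases seq[pos:pos+tsd_len] flank the element as an exact direct repeat.
    """
    if not (0 <= pos <= len(seq) - tsd_len):
        raise ValueError("insertion position out of range")
    tsd = seq[pos:pos + tsd_len]
    if "N" in tsd or "N" in seq[max(0, pos - 1):pos + tsd_len + 1]:
        raise ValueError("cannot insert into an N run")
    derived = seq[:pos + tsd_len] + element + seq[pos:]
    payload = {
        "pos": pos, "tsd_len": tsd_len, "tsd_seq": tsd, "element": element,
        "element_interval_derived": [pos + tsd_len, pos + tsd_len + len(element)],
    }
    record = (log.add("te_insertion", **payload) if log is not None
              else EventRecord("te_insertion", 0, payload))
    return derived, record


@dataclass(frozen=True)
class FillerSpec:
    side: str           # 'upstream' | 'downstream'
    offset: int         # bp from the deletion endpoint to the donor edge
    length: int
    strand: str         # '+' | '-'


def _sample_resection(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def apply_excision_nhej(seq: str, element_interval: tuple, config: SimConfig,
                        rng: np.random.Generator,
                        log: Optional[EventTruthLog] = None,
                        fillers: Optional[Sequence[FillerSpec]] = None,
                        resection: Optional[tuple] = None):
    """Abortive excision: remove the element, resect both ends, repair by
    NHEJ inserting filler fragments copied from near the break ends.

    Resection lengths are geometric with mean ``config.resection_mean``
    unless given explicitly; out-of-bounds resections are resampled (and the
    resample count logged).  Filler fragments (``config.filler_frag_count``
    of them, or an explicit ``fillers`` list) are copied, strand-adjusted,
    from within ``config.filler_window`` bp of either deletion endpoint.
    """
    e0, e1 = element_interval
    if not (0 <= e0 <= e1 <= len(seq)):
        raise ValueError("element interval out of range")
    resamples = 0
    margin = config.filler_window
    if resection is not None:
        r_left, r_right = resection
    else:
        while True:
            r_left = _sample_resection(rng, config.resection_mean)
            r_right = _sample_resection(rng, config.resection_mean)
            if e0 - r_left >= margin and e1 + r_right <= len(seq) - margin:
                break
            resamples += 1
    d0, d1 = e0 - r_left, e1 + r_right
    if not (margin <= d0 and d1 <= len(seq) - margin):
        raise ValueError("resection exceeds sequence bounds")

    if fillers is None:
        specs = []
        for _ in range(config.filler_frag_count):
            lo, hi = config.filler_len_range
            length = int(rng.integers(lo, hi + 1))
            side = "downstream" if rng.random() < 0.5 else "upstream"
            offset = int(rng.integers(0, config.filler_window - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            specs.append(FillerSpec(side, offset, length, strand))
    else:
        specs = list(fillers)

    pieces = []
    frag_payload = []
    for spec in specs:
        if spec.side == "downstream":
            donor = seq[d1 + spec.offset: d1 + spec.offset + spec.length]
        else:
            donor = seq[d0 - spec.offset - spec.length: d0 - spec.offset]
        inserted = donor if spec.strand == "+" else revcomp(donor)
        pieces.append(inserted)
        frag_payload.append(
            {"seq": inserted, "donor_seq": donor, "side": spec.side,
             "offset": spec.offset, "length": spec.length, "strand": spec.strand}
        )
    insert = "".join(pieces)
    derived = seq[:d0] + insert + seq[d1:]
    payload = {
        "element_interval": [e0, e1],
        "deletion": [d0, d1],
        "resection": [r_left, r_right],
        "resamples": resamples,
        "insert": insert,
        "fragments": frag_payload,
    }
    record = (log.add("excision_nhej", **payload) if log is not None
              else EventRecord("excision_nhej", 0, payload))
    return derived, record


def apply_unequal_crossover(hapA: str, hapB: str, anchor_len: int,
                            misalignment: int, rng: np.random.Generator,
                            period: int, array_start: int, array_copies: int,
                            log: Optional[EventTruthLog] = None,
                            max_tries: int = 200):
    """Crossover at a shared exact anchor with copy misalignment.

    The product is hapA[:x] + hapB[y:], where x and y are the 3' ends of the
    same ``anchor_len``-bp anchor in copies i and i - misalignment of the two
    haplotypes.  misalignment > 0 duplicates units (the product gains copies)
    and misalignment < 0 deletes units.  Raises when no mutation-free shared
    anchor can be found.
    """
    if anchor_len < 1:
        raise ValueError("anchor_len must be positive")
    lo_copy = max(0, misalignment)
    hi_copy = min(array_copies, array_copies + misalignment)
    if lo_copy >= hi_copy:
        raise ValueError("misalignment exceeds array size")
    for _ in range(max_tries):
        copy_a = int(rng.integers(lo_copy, hi_copy))
        copy_b = copy_a - misalignment
        phase = int(rng.integers(0, period - anchor_len))
        xa = array_start + copy_a * period + phase
        xb = array_start + copy_b * period + phase
        anchor_a = hapA[xa:xa + anchor_len]
        anchor_b = hapB[xb:xb + anchor_len]
        if anchor_a == anchor_b and "N" not in anchor_a:
            x = xa + anchor_len
            y = xb + anchor_len
            product = hapA[:x] + hapB[y:]
            payload = {
                "anchor_seq": anchor_a, "anchor_len": anchor_len,
                "misalignment": misalignment,
                "pos_a": xa, "pos_b": xb,
                "breakpoint": x,   # product coordinate of the parental switch
            }
            record = (log.add("unequal_crossover", **payload) if log is not None
                      else EventRecord("unequal_crossover", 0, payload))
            return product, record
    raise ValueError(
        f"no shared exact anchor of {anchor_len} bp found in {max_tries} tries"
    )


def apply_tandem_duplication(seq: str, unit_interval: tuple,
                             log: Optional[EventTruthLog] = None):
    """Duplicate seq[s:e) in tandem (the unequal-crossover gain product)."""
    s, e = unit_interval
    if not (0 <= s < e <= len(seq)):
        raise ValueError("unit interval out of range")
    derived = seq[:e] + seq[s:e] + seq[e:]
    payload = {"unit_interval": [s, e], "period": e - s}
    record = (log.add("tandem_duplication", **payload) if log is not None
              else EventRecord("tandem_duplication", 0, payload))
    return derived, record


def apply_anchored_deletion(seq: str, deletion: tuple, anchor_len: int,
                            log: Optional[EventTruthLog] = None):
    """Plant an exact anchor at both deletion endpoints, then delete.

    Returns (ancestor', derived, record): the ancestor is first modified so
    that the ``anchor_len`` bases ending at both endpoints are identical
    (the shared repeat unequal crossover acts on), then [d0, d1) is deleted.
    """
    d0, d1 = deletion
    if not (anchor_len <= d0 < d1 <= len(seq)):
        raise ValueError("deletion interval out of range")
    if d1 - d0 < anchor_len:
        raise ValueError("deletion shorter than the anchor")
    anchor = seq[d1 - anchor_len:d1]
    ancestor = seq[:d0 - anchor_len] + anchor + seq[d0:]
    derived = ancestor[:d0] + ancestor[d1:]
    payload = {"deletion": [d0, d1], "anchor_len": anchor_len,
               "anchor_seq": anchor}
    record = (log.add("anchored_deletion", **payload) if log is not None
              else EventRecord("anchored_deletion", 0, payload))
    return ancestor, derived, record


# ---------------------------------------------------------------------------
# 3' RACE read simulation
# ---------------------------------------------------------------------------

def default_race_sites() -> dict:
    """An 18-site cleavage distribution spanning positions 141-329 after the
    stop codon with a 36% modal site at 301 (the shape reported for a
    transposon-free maize 3' UTR)."""
    minor = [141, 152, 163, 174, 185, 196, 207, 218, 229, 240,
             251, 262, 273, 284, 315, 329]
    dist = {pos: 0.032 for pos in minor}
    dist[298] = 0.128
    dist[301] = 0.36
    assert abs(sum(dist.values()) - 1.0) < 1e-9
    return dist


def canonical_site(ref: str, stop_pos: int, pos: int) -> int:
    """Shift a cleavage position 3' over reference A's (maximal templated
    extension), giving the canonical reported position."""
    end = stop_pos + pos - 1
    while end + 1 < len(ref) and ref[end + 1] == "A":
        end += 1
    return end - stop_pos + 1


def simulate_race_reads(ref_3utr, stop_pos: int, config: SimConfig,
                        rng: np.random.Generator,
                        log: Optional[EventTruthLog] = None):
    """Draw reads multinomially from the cleavage-site distribution.

    Each read is the templated sequence from the reference start to its
    cleavage position plus an untemplated poly(A) tail (length uniform in
    ``tail_len_range``).  Site positions are canonicalized under the maximal
    templated-extension rule before logging, so truth positions are exactly
    what an extension-aware mapper reports.  Returns (reads, truth) where
    reads is a list of (id, seq) and truth maps position -> read count.
    """
    ref = ref_3utr.seq if hasattr(ref_3utr, "seq") else str(ref_3utr).upper()
    dist = config.race_site_distribution or default_race_sites()
    canon: dict = {}
    for pos, prob in sorted(dist.items()):
        cpos = canonical_site(ref, stop_pos, pos)
        canon[cpos] = canon.get(cpos, 0.0) + prob
    positions = sorted(canon)
    probs = np.array([canon[p] for p in positions])
    probs = probs / probs.sum()
    counts = rng.multinomial(config.n_reads, probs)
    reads = []
    truth: dict = {}
    k = 0
    lo, hi = config.tail_len_range
    for pos, count in zip(positions, counts):
        if count:
            truth[pos] = int(count)
        end = stop_pos + pos - 1
        for _ in range(count):
            tail = "A" * int(rng.integers(lo, hi + 1))
            reads.append((f"read_{k}", ref[:end + 1] + tail))
            k += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    if log is not None:
        log.add("race_reads", stop_pos=stop_pos, truth=truth,
                n_reads=config.n_reads)
    return reads, truth


# ---------------------------------------------------------------------------
# Whole-locus simulation and replay
# ---------------------------------------------------------------------------

def simulate_locus(config: SimConfig, n_events: int = 3,
                   te_element: Optional[str] = None):
    """Build an ancestor and derive one allele by a mix of logged events.

    Events (TE insertion, excision+NHEJ, tandem duplication, anchored
    deletion) are placed at well-separated loci and applied right-to-left so
    earlier edits do not shift later coordinates; the truth log lists them
    in application order.  Returns (ref_record, alt_record, truth_log).
    """
    rng = np.random.default_rng(config.seed)
    record, features, _ = build_ancestor(config, rng)
    seq = record.seq
    log = EventTruthLog(config=config)
    te = te_element or random_seq(rng, 400)

    margin = config.filler_window + 100      # room for donors and resection
    slot_width = 400 + len(te) + 2 * margin
    usable = len(seq) - 2 * config.flank_len
    n_slots = usable // slot_width
    if n_slots < 1:
        raise ValueError(
            f"locus too small for events (needs >= {slot_width} bp between "
            "flanks)"
        )
    n_events = min(n_events, n_slots)
    slots = np.sort(
        rng.choice(n_slots, size=n_events, replace=False)
    )[::-1]
    kinds = ["te_insertion", "excision_nhej", "tandem_duplication",
             "anchored_deletion"]
    plans = []
    for slot in slots:
        base = config.flank_len + int(slot) * slot_width + margin
        kind = kinds[int(rng.integers(0, len(kinds)))]
        span = int(rng.integers(150, 400))
        lo, hi = config.tsd_len_range
        tsd = int(rng.integers(lo, hi + 1))
        plans.append((base, kind, span, tsd))

    # anchored deletions act on shared repeats that are part of the ancestral
    # state: plant their anchors in the ancestor before deriving
    k = config.uxo_anchor_len
    for base, kind, span, _ in plans:
        if kind == "anchored_deletion":
            d0, d1 = base, base + span
            seq = seq[:d0 - k] + seq[d1 - k:d1] + seq[d0:]
    record = SequenceRecord(record.id, seq, record.description)

    for base, kind, span, tsd in plans:   # right-to-left: slots were sorted desc
        if kind == "te_insertion":
            seq, _ = apply_te_insertion(seq, te, base, tsd, log)
        elif kind == "excision_nhej":
            # clamp resection to the slot margin so events stay independent
            res = (min(_sample_resection(rng, config.resection_mean), 100),
                   min(_sample_resection(rng, config.resection_mean), 100))
            seq, _ = apply_excision_nhej(seq, (base, base + span), config, rng,
                                         log, resection=res)
        elif kind == "tandem_duplication":
            seq, _ = apply_tandem_duplication(seq, (base, base + span), log)
        else:
            d0, d1 = base, base + span
            log.add("anchored_deletion", deletion=[d0, d1], anchor_len=k,
                    anchor_seq=seq[d1 - k:d1], planted_in_ancestor=True)
            seq = seq[:d0] + seq[d1:]
    alt = SequenceRecord("derived", seq, "simulated derived allele")
    log.derived_allele_ids.append(alt.id)
    return record, alt, log


def replay(ancestor: str, log: EventTruthLog) -> str:
    """Apply the logged events to the ancestor; must reproduce the derived
    allele byte-for-byte."""
    seq = ancestor
    for rec in log.records:
        p = rec.payload
        if rec.event_kind == "te_insertion":
            pos, tsd = p["pos"], p["tsd_len"]
            seq = seq[:pos + tsd] + p["element"] + seq[pos:]
        elif rec.event_kind == "excision_nhej":
            d0, d1 = p["deletion"]
            seq = seq[:d0] + p["insert"] + seq[d1:]
        elif rec.event_kind == "tandem_duplication":
            s, e = p["unit_interval"]
            seq = seq[:e] + seq[s:e] + seq[e:]
        elif rec.event_kind == "anchored_deletion":
            d0, d1 = p["deletion"]
            if not p.get("planted_in_ancestor"):
                k = p["anchor_len"]
                seq = seq[:d0 - k] + p["anchor_seq"] + seq[d0:]  # plant anchor
            seq = seq[:d0] + seq[d1:]
        elif rec.event_kind == "unequal_crossover":
            raise ValueError("crossover replay requires both haplotypes")
        elif rec.event_kind == "race_reads":
            continue
        else:
            raise ValueError(f"unknown event kind {rec.event_kind!r}")
    return seq
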