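"""Synthetic sequence data with known ground truth.

Three generators emulate the data regimes the toolkit is exercised on:

* :func:`gen_ogt_proteomes` — two-class "proteomes" whose residue
  compositions differ by a tunable effect size ``delta``: thermophile-class
  sequences re-allocate ``delta`` probability mass onto a designated residue
  set (default IVYWREL plus the charged residues D, E, K, R — established
  thermostability correlates), with OGT drawn per class (uniform 55-75 C
  vs 25-37 C).
* :func:`gen_homolog_family` — a star phylogeny around a sampled ancestor:
  descendants accumulate per-site substitutions and geometric indels while
  a serine-hydrolase-like catalytic motif (G-x-S-x-G plus distal H and D)
  stays intact in actives and is ablated in inactives; the true alignment
  is tracked through every indel event.
* :func:`plant_dipeptide_signal` / :func:`gen_ogt_table` — label-associated
  g-gap dipeptide insertions and partial OGT tables.

Every generator draws from ``numpy.random.default_rng([seed, stream_id])``
with a fixed stream id per operation, so outputs are byte-identical across
runs and adding one generator call never perturbs another.

These data are simpler than real proteomes in known ways (i.i.d. residues,
star phylogeny, no domain structure); see the methods note for what
passing tests on them does and does not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .features import ConstantsTable
from .io import Alignment, CANONICAL_AA, SequenceRecord

_STREAMS = {
    "proteomes": 1,
    "family": 2,
    "plant": 3,
    "ogt_table": 4,
}

DESIGNATED_SET = "IVYWRELDK"  # IVYWREL union {D,E,K,R} as a residue set
# (R and E already appear in IVYWREL)
DESIGNATED_SET = "".join(sorted(set("IVYWREL") | set("DEKR")))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_background() -> dict:
    """SwissProt-like residue frequencies (normalized)."""
    bg = ConstantsTable.default().background
    total = sum(bg.values())
    return {a: v / total for a, v in bg.items()}


@dataclass
class MotifSpec:
    """Catalytic-motif constraints: a core pattern plus distal residues.

    ``pattern`` uses 'x' for unconstrained positions (default the serine
    hydrolase nucleophile elbow G-x-S-x-G); ``distal`` residues are placed
    downstream at fixed fractions of the sequence length (the His and Asp
    of a Ser-His-Asp triad by default).
    """

    pattern: str = "GxSxG"
    distal: tuple = ("H", "D")

    def length(self) -> int:
        return len(self.pattern)


@dataclass
class SyntheticConfig:
    n_per_class: int = 200
    length: tuple = (80, 200)          # uniform inclusive range
    background: dict | None = None     # None -> SwissProt-like
    delta: float = 0.1                 # composition effect size
    designated: str = DESIGNATED_SET
    ogt_positive: tuple = (55.0, 70.0)  # inside the thermophilic band
    ogt_negative: tuple = (25.0, 37.0)
    mutation_rate: float = 0.05        # per-site substitution probability
    inactive_extra_rate: float = 0.0   # added substitution rate for inactives
    #   (relaxed purifying selection on non-functional homologs; 0 = same rate)
    indel_rate: float = 0.01           # per-site indel initiation probability
    indel_mean: float = 1.5            # geometric mean indel length
    motif: MotifSpec = field(default_factory=MotifSpec)
    n_active: int = 20
    n_inactive: int = 20
    unmapped_fraction: float = 0.0
    seed: int = 0

    def resolved_background(self) -> tuple[np.ndarray, str]:
        bg = self.background or default_background()
        alphabet = CANONICAL_AA
        p = np.array([bg[a] for a in alphabet], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ConfigError("background frequencies must be a distribution")
        return p / p.sum(), alphabet


def shifted_frequencies(p: np.ndarray, alphabet: str, designated: str,
                        delta: float) -> np.ndarray:
    """Move ``delta`` probability mass onto the designated set, proportionally."""
    mask = np.array([a in set(designated) for a in alphabet])
    p_s = p[mask].sum()
    if delta < 0 or delta > 1 - p_s:
        raise ConfigError(
            f"delta={delta} infeasible for designated-set mass {p_s:.3f}"
        )
    out = p.copy()
    if delta == 0:
        return out
    out[mask] *= 1.0 + delta / p_s
    out[~mask] *= 1.0 - delta / (1.0 - p_s)
    return out / out.sum()


def _sample_seq(rng, p: np.ndarray, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length, p=p))


@dataclass
class SyntheticTruth:
    """Ground truth per generated sequence, keyed by id."""

    per_sequence: dict = field(default_factory=dict)
    alignment: Alignment | None = None
    ancestor: str | None = None

    def __getitem__(self, key):
        return self.per_sequence[key]


def gen_ogt_proteomes(config: SyntheticConfig) -> tuple[list, SyntheticTruth]:
    """Two-class compositionally shifted sequence sets with per-class OGT."""
    rng = _rng(config.seed, "proteomes")
    p, alphabet = config.resolved_background()
    p_pos = shifted_frequencies(p, alphabet, config.designated, config.delta)
    lo, hi = config.length
    records, truth = [], SyntheticTruth()
    for cls, freqs, ogt_range, prefix in (
        ("thermophilic", p_pos, config.ogt_positive, "thermo"),
        ("mesophilic", p, config.ogt_negative, "meso"),
    ):
        for i in range(config.n_per_class):
            L = int(rng.integers(lo, hi + 1))
            seq = _sample_seq(rng, freqs, alphabet, L)
            ogt = float(rng.uniform(*ogt_range))
            rid = f"{prefix}_{i:04d}"
            records.append(SequenceRecord(id=rid, residues=seq, ogt=ogt))
            truth.per_sequence[rid] = {"class_label": cls, "ogt": ogt}
    return records, truth


def _place_motif(rng, seq: list, motif: MotifSpec, alphabet: str):
    """Write the motif into a sequence.

    Returns (constrained positions -> residue, indel-protected positions).
    The protected span covers the whole core pattern (wildcards included,
    so motif spacing survives) plus the distal sites.
    """
    L = len(seq)
    core_start = L // 2 - motif.length() // 2
    positions = {}
    for off, c in enumerate(motif.pattern):
        if c != "x":
            positions[core_start + off] = c
    protected = set(range(core_start, core_start + motif.length()))
    anchor = core_start + motif.length()
    for j, c in enumerate(motif.distal):
        pos = anchor + int((L - anchor - 1) * (j + 1) / (len(motif.distal) + 1))
        positions[pos] = c
        protected.add(pos)
    for pos, c in positions.items():
        seq[pos] = c
    return positions, protected


def gen_homolog_family(config: SyntheticConfig) -> tuple[list, Alignment, SyntheticTruth]:
    """Star-phylogeny homolog family with an active/inactive motif split.

    Returns (records, true alignment, truth).  Actives carry the intact
    motif (their motif sites are immune to substitution); inactives have
    every motif site randomized to a different residue.  Indels never touch
    motif sites.  ``activity_value`` is positive for actives, 0 otherwise.
    """
    rng = _rng(config.seed, "family")
    p, alphabet = config.resolved_background()
    lo, hi = config.length
    if config.motif.length() + 10 > lo:
        raise ConfigError("motif does not fit within the minimum sequence length")
    L = int(rng.integers(lo, hi + 1))
    ancestor = list(_sample_seq(rng, p, alphabet, L))
    motif_positions, protected = _place_motif(rng, ancestor, config.motif, alphabet)
    letters = list(alphabet)

    n_total = config.n_active + config.n_inactive
    per_site_desc = []   # per descendant: list over ancestor sites of residue|None
    inserts_desc = []    # per descendant: dict site -> inserted string (after site)
    meta = []
    for d in range(n_total):
        active = d < config.n_active
        rate = config.mutation_rate + (0.0 if active else config.inactive_extra_rate)
        residues = []
        inserts: dict[int, str] = {}
        ablated = {}
        if not active:
            for pos, c in motif_positions.items():
                choices = [x for x in letters if x != c]
                ablated[pos] = choices[int(rng.integers(0, len(choices)))]
        for i, anc in enumerate(ancestor):
            if i in motif_positions:
                residues.append(ablated.get(i, anc) if not active else anc)
            elif i in protected:
                # wildcard motif slot: substitutions allowed, indels not
                c = anc
                if rng.random() < rate:
                    c = letters[int(rng.integers(0, len(letters)))]
                residues.append(c)
            else:
                if rng.random() < config.indel_rate:
                    # deletion event: drop this site
                    residues.append(None)
                else:
                    c = anc
                    if rng.random() < rate:
                        c = letters[int(rng.integers(0, len(letters)))]
                    residues.append(c)
                if (rng.random() < config.indel_rate
                        and (i + 1) not in protected and i not in protected):
                    n_ins = int(rng.geometric(1.0 / config.indel_mean))
                    inserts[i] = _sample_seq(rng, p, alphabet, n_ins)
        per_site_desc.append(residues)
        inserts_desc.append(inserts)
        meta.append(active)

    # build the true alignment: ancestor columns + insert blocks after each site
    max_ins = [max((len(ins.get(i, "")) for ins in inserts_desc), default=0)
               for i in range(L)]
    records, rows, ids = [], [], []
    truth = SyntheticTruth()
    for d in range(n_total):
        active = meta[d]
        rid = f"{'act' if active else 'inact'}_{d:03d}"
        row = []
        for i in range(L):
            site = per_site_desc[d][i]
            row.append(site if site is not None else "-")
            ins = inserts_desc[d].get(i, "")
            row.append(ins + "-" * (max_ins[i] - len(ins)))
        aligned = "".join(row)
        seq = aligned.replace("-", "")
        activity = float(rng.gamma(2.0, 1.0) + 0.1) if active else 0.0
        rec = SequenceRecord(
            id=rid, residues=seq,
            activity_label="active" if active else "inactive",
            activity_value=activity,
        )
        records.append(rec)
        rows.append(aligned)
        ids.append(rid)
        # motif coordinates in the descendant's own (ungapped) frame
        coords = {}
        for pos in motif_positions:
            col = sum(1 + max_ins[i] for i in range(pos))  # column of site pos
            coords[pos] = len(aligned[:col].replace("-", ""))
        truth.per_sequence[rid] = {
            "active": active,
            "family": "fam0",
            "activity_value": activity,
            "motif_sites": dict(motif_positions),
            "motif_coords": coords,
        }
    aln = Alignment(ids, rows)
    truth.alignment = aln
    truth.ancestor = "".join(ancestor)
    return records, aln, truth


def plant_dipeptide_signal(records, descriptors, count: int, seed: int,
                           positive_ids) -> tuple[list, SyntheticTruth]:
    """Write g-gap dipeptide occurrences into positive records.

    For each positive record and each descriptor (a, g, b), ``count``
    non-overlapping occurrences are written at random positions (slot i
    gets a, slot i+g+1 gets b).  Negative records are returned unchanged.
    """
    if count < 1:
        raise ConfigError("count must be >= 1")
    rng = _rng(seed, "plant")
    positive_ids = set(positive_ids)
    out, truth = [], SyntheticTruth()
    for rec in records:
        if rec.id not in positive_ids:
            out.append(rec)
            continue
        seq = list(rec.residues)
        used: set[int] = set()
        placed = {}
        for a, g, b in descriptors:
            spots = []
            starts = list(range(len(seq) - g - 1))
            rng.shuffle(starts)
            for i in starts:
                if i in used or (i + g + 1) in used:
                    continue
                seq[i] = a
                seq[i + g + 1] = b
                used.update((i, i + g + 1))
                spots.append(i)
                if len(spots) == count:
                    break
            if len(spots) < count:
                raise ConfigError(
                    f"record {rec.id}: insufficient room to plant {count} x "
                    f"{a}(x){g}{b}"
                )
            placed[f"{a}|{g}|{b}"] = spots
        out.append(replace(rec, residues="".join(seq)))
        truth.per_sequence[rec.id] = {"planted": placed}
    return out, truth


def gen_ogt_table(records, unmapped_fraction: float, seed: int) -> dict:
    """OGT table covering a (1 - fraction) subset of record ids, uniformly."""
    if not 0 <= unmapped_fraction <= 1:
        raise ConfigError("unmapped_fraction must be in [0, 1]")
    rng = _rng(seed, "ogt_table")
    ids = [r.id for r in records]
    n_mapped = round((1.0 - unmapped_fraction) * len(ids))
    chosen = sorted(rng.choice(len(ids), size=n_mapped, replace=False).tolist())
    table = {}
    for j in chosen:
        rec = records[j]
        if rec.ogt is None:
            raise ConfigError(f"record {rec.id} has no OGT to tabulate")
        table[rec.id] = float(rec.ogt)
    return table


def gen_triage_scenario(seed: int = 0):
    """A mining database with a fully known selectable-candidate set.

    Twenty homolog-family members are planted among 80 unrelated background
    decoys.  The family ancestor is drawn from a strongly thermophile-biased
    composition (delta = 0.35 on the designated set) so that members routed
    through the classifier fallback are unambiguously on the thermophilic
    side of any sensibly trained decision boundary; a classifier for this
    scenario should be trained on proteomes generated at the same delta
    (see ``classifier_delta`` in the returned dict).

    * f01..f10: measured OGT 60 C, source "dbA" (f09/f10 duplicate the
      mature sequences of f01/f02 behind distinct signal peptides,
      exercising dedup -- either member of a pair may be the surviving
      representative, so truth is expressed as groups);
    * f11..f14: measured OGT 30 C ("dbA") -- fail thermotolerance;
    * f15..f18: absent from the OGT table ("dbA") -- classifier fallback;
    * f19..f20: OGT 60 C but source "dbB", whose score window excludes
      family-strength scores.

    With windows dbA=(10, inf), dbB=(-inf, 10), OGT threshold 50 and search
    threshold 10 bits, exactly 12 candidates are selectable.  Returns a dict
    with records, seed_alignment, ogt_table, expected_groups (list of id
    tuples; exactly one id per group must be selected), classifier_delta,
    and the family config.
    """
    delta_bias = 0.35
    p, alphabet = SyntheticConfig().resolved_background()
    biased = shifted_frequencies(p, alphabet, DESIGNATED_SET, delta_bias)
    biased_bg = {a: float(v) for a, v in zip(alphabet, biased)}
    fam_cfg = SyntheticConfig(
        seed=seed, n_active=20, n_inactive=0, length=(90, 110),
        mutation_rate=0.05, background=biased_bg,
    )
    members, seed_aln, _ = gen_homolog_family(fam_cfg)
    rng = _rng(seed, "proteomes")

    records = []
    ogt_table: dict[str, float] = {}
    expected_groups = []
    for i, rec in enumerate(members, start=1):
        rid = f"f{i:02d}"
        source = "dbB" if i >= 19 else "dbA"
        residues = rec.residues
        sp_end = None
        if i in (9, 10):
            # duplicate of member i-8's mature sequence, distinct signal peptide
            donor = members[i - 9]
            sp = _sample_seq(rng, p, alphabet, 12 + i)
            residues = sp + donor.residues
            sp_end = len(sp)
        records.append(SequenceRecord(id=rid, residues=residues, source=source,
                                      signal_peptide_end=sp_end))
        if i <= 10 or i >= 19:
            ogt_table[rid] = 60.0
        elif i <= 14:
            ogt_table[rid] = 30.0
        # 15..18 left unmapped -> classifier fallback
    expected_groups = [("f01", "f09"), ("f02", "f10")] + [
        (f"f{i:02d}",) for i in list(range(3, 9)) + list(range(15, 19))
    ]
    for j in range(80):
        L = int(rng.integers(90, 111))
        records.append(SequenceRecord(
            id=f"decoy_{j:03d}", residues=_sample_seq(rng, p, alphabet, L),
            source="dbA" if j % 2 == 0 else "dbB",
        ))
    return {
        "records": records,
        "seed_alignment": seed_aln,
        "ogt_table": ogt_table,
        "expected_groups": expected_groups,
        "classifier_delta": delta_bias,
        "family_config": fam_cfg,
    }
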