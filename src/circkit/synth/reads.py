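"""Paired-end read simulation for circRNA pipelines.

Fragments are drawn from a pool of spliced linear transcripts (one per
gene) and circular transcripts (one per planted circRNA).  Circular
fragments start anywhere around the circle and wrap across the backsplice
junction; a fragment longer than the circle is drawn from a tandem
concatenation of the circular sequence.  RNase R treatment is modelled as
uniform binomial survival of linear fragments (default 2%) with circular
fragments untouched.  Read names carry the ground truth (origin
transcript, whether the fragment wraps the BSJ), so detector recall and
precision can be scored exactly without alignment.

The library is simulated unstranded: each fragment is sequenced from a
random strand, which for paired ends amounts to swapping the two mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import CircTruth, GenomeModel, circular_sequence, revcomp

READ_LENGTH = 150


@dataclass(frozen=True)
class ReadOrigin:
    """Parsed ground truth carried in a simulated read name."""

    kind: str  # "lin" or "circ"
    ref_id: str  # gene_id or circ_id
    spans_bsj: bool
    start: int  # fragment start on the (possibly circular) transcript
    frag_len: int


def encode_read_name(sample_id: str, serial: int, origin: ReadOrigin) -> str:
    return (
        f"{sample_id}.{serial}|org={origin.kind}:{origin.ref_id}"
        f"|bsj={int(origin.spans_bsj)}|pos={origin.start}|len={origin.frag_len}"
    )


def parse_read_name(name: str) -> ReadOrigin:
    head, *fields = name.split("|")
    kv = dict(f.split("=", 1) for f in fields)
    kind, ref_id = kv["org"].split(":", 1)
    return ReadOrigin(
        kind=kind,
        ref_id=ref_id,
        spans_bsj=bool(int(kv["bsj"])),
        start=int(kv["pos"]),
        frag_len=int(kv["len"]),
    )


@dataclass
class ReadSet:
    """Paired 150 nt mates with truth-tagged names and sample metadata."""

    names: list[str]
    mates1: list[str]
    mates2: list[str]
    sample_id: str = "sample"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.mates1, self.mates2))

    def origins(self) -> list[ReadOrigin]:
        return [parse_read_name(n) for n in self.names]


def gene_abundances(genome: GenomeModel, seed: int = 0, log2_sd: float = 1.0) -> dict[str, float]:
    """Lognormal relative molar abundances, one per gene.

    Drawn from a seed separate from the library seed so that the same
    expression programme can be shared across replicates and states.
    """
    rng = np.random.default_rng(seed)
    return {g.gene_id: float(2.0 ** rng.normal(0.0, log2_sd)) for g in genome.genes}


def _transcript_pool(
    genome: GenomeModel,
    truths: list[CircTruth],
    state: str,
    abundances: dict[str, float],
    circ_scale: float,
) -> list[tuple[str, str, str, bool, float]]:
    """Fragment-sampling pool: (kind, id, sequence, circular?, weight).

    Weights are molar abundance times transcript length (every position
    can start a fragment; on a circle, literally every position).
    """
    pool: list[tuple[str, str, str, bool, float]] = []
    for g in genome.genes:
        seq = genome.spliced_sequence(g)
        pool.append(("lin", g.gene_id, seq, False, abundances[g.gene_id] * len(seq)))
    for t in truths:
        seq = circular_sequence(genome, t)
        mult = float(t.copies_per_state.get(state, t.copies_per_state.get("default", 1.0)))
        molar = t.clr_truth * abundances[t.gene_id] * mult * circ_scale
        pool.append(("circ", t.circ_id, seq, True, molar * len(seq)))
    return pool


def transcript_weights(
    genome: GenomeModel,
    truths: list[CircTruth],
    state: str = "default",
    abundances: dict[str, float] | None = None,
    abundance_seed: int = 0,
    circ_scale: float = 1.0,
) -> tuple[float, float]:
    """(linear, circular) total sampling weight of a library's pool.

    Lets an experiment hold absolute linear output constant across
    states: scaling the depth by the ratio of total weights keeps the
    expected linear fragment count fixed while the circular share moves.
    """
    if abundances is None:
        abundances = gene_abundances(genome, seed=abundance_seed)
    pool = _transcript_pool(genome, truths, state, abundances, circ_scale)
    w_lin = sum(w for kind, _i, _s, _c, w in pool if kind == "lin")
    w_circ = sum(w for kind, _i, _s, _c, w in pool if kind == "circ")
    return w_lin, w_circ


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_library(
    genome: GenomeModel,
    truths: list[CircTruth],
    state: str = "default",
    *,
    rnase_r: bool = False,
    depth: int = 10_000,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str | None = None,
    abundances: dict[str, float] | None = None,
    abundance_seed: int = 0,
    circ_scale: float = 1.0,
    linear_survival: float = 0.02,
    read_length: int = READ_LENGTH,
    fragment_len_mean: float = 300.0,
    fragment_len_sd: float = 40.0,
) -> ReadSet:
    """Simulate one paired-end library.

    ``depth`` is the number of fragments drawn before RNase R treatment;
    untreated libraries therefore contain exactly ``depth`` fragments,
    while treated libraries keep every circular fragment and each linear
    fragment independently with probability ``linear_survival``.

    A circRNA's molar abundance is
    ``clr_truth * host abundance * copies_per_state[state] * circ_scale``,
    so the planted circular-to-linear ratio is expressed at the
    junction-count level and ``circ_scale`` can impose a global
    circularization shift between states without touching linear output.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0 <= error_rate < 0.05):
        raise ValueError("error_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    if sample_id is None:
        sample_id = f"{state}_s{seed}"
    if abundances is None:
        abundances = gene_abundances(genome, seed=abundance_seed)
    pool = _transcript_pool(genome, truths, state, abundances, circ_scale)

    meta = {
        "state": state,
        "rnase_r": rnase_r,
        "seed": seed,
        "depth": depth,
        "error_rate": error_rate,
    }
    empty = ReadSet([], [], [], sample_id=sample_id, metadata=meta)
    if depth == 0:
        return empty

    weights = np.array([p[4] for p in pool])
    counts = rng.multinomial(depth, weights / weights.sum())
    if rnase_r:
        for i, (kind, *_rest) in enumerate(pool):
            if kind == "lin":
                counts[i] = rng.binomial(counts[i], linear_survival)

    names: list[str] = []
    mates1: list[str] = []
    mates2: list[str] = []
    serial = 0
    min_flen = read_length
    for (kind, ref_id, seq, is_circ, _w), n in zip(pool, counts):
        if n == 0:
            continue
        L = len(seq)
        flens = np.clip(
            np.rint(rng.normal(fragment_len_mean, fragment_len_sd, size=n)).astype(int),
            min_flen,
            None,
        )
        if is_circ:
            starts = rng.integers(0, L, size=n)
        else:
            flens = np.minimum(flens, L)
            starts = rng.integers(0, L - flens + 1)
        flips = rng.random(n) < 0.5
        for s, fl, flip in zip(starts, flens, flips):
            s, fl = int(s), int(fl)
            if is_circ:
                reps = (s + fl + L - 1) // L
                frag = (seq * max(reps, 1))[s : s + fl]
                spans = s + fl > L  # wraps across the backsplice
            else:
                frag = seq[s : s + fl]
                spans = False
            m1 = frag[:read_length]
            m2 = revcomp(frag[-read_length:])
            if flip:
                m1, m2 = m2, m1
            m1 = _mutate(rng, m1, error_rate)
            m2 = _mutate(rng, m2, error_rate)
            serial += 1
            names.append(
                encode_read_name(sample_id, serial, ReadOrigin(kind, ref_id, spans, s, fl))
            )
            mates1.append(m1)
            mates2.append(m2)
    return ReadSet(names, mates1, mates2, sample_id=sample_id, metadata=meta)
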