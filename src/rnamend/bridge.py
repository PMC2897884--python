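"""Probe-seeded consensus assembly of reads: bridging flags, extending ends.

The assembler never aligns reads to anything.  It looks up an exact
18-mer probe in the read set (both orientations), tallies the bases each
matching read carries immediately after the probe, and emits the strict
majority base per position ('N' on a tie or with no coverage).  Chaining
these 18-base consensus chunks grows a contig until a downstream probe is
found (bridging) or the iteration / unknown-base budgets run out
(extension).  With the defaults, bridging allows 27 iterations and 6 'N'
calls; terminus extension allows a single 'N'.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .io_formats import SequenceRecord, reverse_complement

PROBE_LEN = 18
DEFAULT_MAX_LOOK = 27
DEFAULT_MAX_N = 6
DEFAULT_EXTENSION_MAX_N = 1

STATUS_FOUND = "end_probe_found"
STATUS_MAX_LOOK = "max_look_exceeded"
STATUS_MAX_N = "max_n_exceeded"
STATUS_NO_READS = "no_reads_matched"


class ReadIndex:
    """Exact-substring lookup over the reads and their reverse complements.

    ``query(p)`` returns every (read index, offset, orientation) whose
    oriented read contains ``p`` at ``offset``; a perfect match is
    required.
    """

    def __init__(self, reads: list[SequenceRecord], probe_len: int = PROBE_LEN):
        self.probe_len = probe_len
        self.read_len = len(reads[0].seq) if reads else 0
        # oriented sequences: (forward, reverse-complement) per read
        self._seqs: list[tuple[str, str]] = [
            (r.seq, reverse_complement(r.seq)) for r in reads
        ]
        self._index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
        for ridx, (fwd, rev) in enumerate(self._seqs):
            for oi, seq in enumerate((fwd, rev)):
                for off in range(len(seq) - probe_len + 1):
                    self._index[seq[off : off + probe_len]].append((ridx, off, oi))

    def query(self, probe: str) -> list[tuple[int, int, int]]:
        if len(probe) != self.probe_len:
            raise ValueError(
                f"probe length {len(probe)} != index probe length {self.probe_len}"
            )
        return self._index.get(probe, [])

    def oriented_seq(self, read_idx: int, orient: int) -> str:
        return self._seqs[read_idx][orient]


@dataclass(frozen=True)
class BridgeResult:
    sequence: str
    status: str
    iterations_used: int
    n_count: int


@dataclass(frozen=True)
class ResolvedFlag:
    flag_index: int
    offset_used: int       # probe offset d in {6, 15, 21}
    sequence: str          # start probe ... end probe, inclusive


@dataclass
class BES:
    """Bridged and Extended Sequence for one gene."""

    gene_id: str
    sequence: str
    bridged_flags: list[ResolvedFlag] = field(default_factory=list)
    unresolved_flags: list[int] = field(default_factory=list)
    upstream_extension_len: int = 0
    downstream_extension_len: int = 0

    @property
    def has_unresolved(self) -> bool:
        return bool(self.unresolved_flags)


def find_next_probe(probe: str, index: ReadIndex) -> str:
    """Consensus chunk of probe-length bases following *probe* in the reads.

    Per position after the probe, the counts of A/C/G/T carried by every
    read matching the probe are tallied; the consensus is the strict
    majority base (> half of the position's calls), else 'N'.  Reads'
    own 'N' bases carry no information and are not tallied.
    """
    plen = index.probe_len
    counts = [defaultdict(int) for _ in range(plen)]
    for ridx, off, orient in index.query(probe):
        seq = index.oriented_seq(ridx, orient)
        tail = seq[off + plen : off + 2 * plen]
        for pos, base in enumerate(tail):
            if base != "N":
                counts[pos][base] += 1
    out = []
    for c in counts:
        total = sum(c.values())
        if total == 0:
            out.append("N")
            continue
        base, best = max(c.items(), key=lambda kv: (kv[1], kv[0]))
        out.append(base if best * 2 > total else "N")
    return "".join(out)


def bridge(
    start_probe: str,
    end_probe: str | None,
    index: ReadIndex,
    max_look: int = DEFAULT_MAX_LOOK,
    max_n: int = DEFAULT_MAX_N,
) -> BridgeResult:
    """Grow a consensus contig from *start_probe* toward *end_probe*.

    With ``end_probe=None`` this is extension mode: the contig grows until
    the budgets stop it and is returned with its trailing run of 'N'
    stripped.  After each appended chunk the whole accumulated sequence is
    scanned for the end probe, so bridges need not be chunk-aligned.
    The success check runs before the budget checks.
    """
    plen = index.probe_len
    if len(start_probe) != plen or "X" in start_probe:
        raise ValueError("invalid start probe")
    if end_probe is not None and (len(end_probe) != plen or "X" in end_probe):
        raise ValueError("invalid end probe")

    seq = start_probe
    iterations = 0
    status = STATUS_MAX_LOOK
    extension = end_probe is None

    if end_probe is not None and end_probe in seq:
        return BridgeResult(
            seq[: seq.index(end_probe) + plen], STATUS_FOUND, 0, seq.count("N")
        )

    while iterations < max_look:
        iterations += 1
        chunk = find_next_probe(seq[-plen:], index)
        seq += chunk
        if end_probe is not None and end_probe in seq:
            seq = seq[: seq.index(end_probe) + plen]
            status = STATUS_FOUND
            break
        if chunk == "N" * plen and iterations == 1:
            status = STATUS_NO_READS
            break
        if seq.count("N") > max_n:
            status = STATUS_MAX_N
            break
    if extension:
        seq = seq.rstrip("N")
    return BridgeResult(seq, status, iterations, seq.count("N"))


def resolve_flag(
    fdm,
    flag_index: int,
    index: ReadIndex,
    offsets: tuple[int, ...] = (6, 15, 21),
    max_look: int = DEFAULT_MAX_LOOK,
    max_n: int = DEFAULT_MAX_N,
) -> ResolvedFlag | None:
    """Bridge one internal flag, retrying probes 6, 15 then 21 bp away.

    The returned spanning sequence runs from the start probe through the
    end probe, replacing the flag and the ``offset + 18`` bp margins on
    each side.  Returns ``None`` when every probe pair fails
    (the flag is unresolved).
    """
    segs = fdm.segments
    if segs[flag_index].kind != "X":
        raise ValueError(f"segment {flag_index} is not a flag")
    if flag_index == 0 or flag_index == len(segs) - 1:
        raise ValueError("terminal flags are extended, not bridged")
    up = segs[flag_index - 1].text
    down = segs[flag_index + 1].text
    plen = index.probe_len
    for d in offsets:
        if len(up) < d + plen or len(down) < d + plen:
            continue
        start_probe = up[-(d + plen) : len(up) - d]
        end_probe = down[d : d + plen]
        if "N" in start_probe or "N" in end_probe:
            continue
        result = bridge(start_probe, end_probe, index, max_look, max_n)
        if result.status == STATUS_FOUND:
            return ResolvedFlag(flag_index, d, result.sequence)
    return None


def assemble_bes(
    fdm,
    index: ReadIndex,
    offsets: tuple[int, ...] = (6, 15, 21),
    max_look: int = DEFAULT_MAX_LOOK,
    max_n: int = DEFAULT_MAX_N,
    extension_max_n: int = DEFAULT_EXTENSION_MAX_N,
) -> BES:
    """Resolve every internal flag and extend both termini.

    The BES is built in transcript orientation: upstream extension, then
    the flag-resolved body, then downstream extension.  Unresolved flags
    stay as 'X' characters (the gene will classify as failed downstream).
    Adjacent bridges may overlap on a short (>= 36 bp) expressed island;
    the overlap is emitted once, taken from the left bridge.
    """
    plen = index.probe_len
    working = fdm.working_sequence()
    flag_positions = [i for i, ch in enumerate(working) if ch == "X"]
    flag_seg_indices = [
        i for i, s in enumerate(fdm.segments) if s.kind == "X"
    ]
    assert len(flag_positions) == len(flag_seg_indices)

    bridged: list[ResolvedFlag] = []
    unresolved: list[int] = []
    parts: list[str] = []
    cursor = 0
    for q, seg_i in zip(flag_positions, flag_seg_indices):
        res = resolve_flag(fdm, seg_i, index, offsets, max_look, max_n)
        if res is None:
            parts.append(working[cursor:q])
            parts.append("X")
            cursor = q + 1
            unresolved.append(seg_i)
            continue
        consumed = res.offset_used + plen
        repl_start = q - consumed
        if repl_start >= cursor:
            parts.append(working[cursor:repl_start])
            parts.append(res.sequence)
        else:
            # previous bridge already covered [repl_start, cursor)
            parts.append(res.sequence[cursor - repl_start :])
        cursor = q + 1 + consumed
        bridged.append(res)
    parts.append(working[cursor:])
    core = "".join(parts)

    up_ext = down_ext = ""
    if len(core) >= plen:
        head = core[:plen]
        if "X" not in head and "N" not in head:
            grown = bridge(
                reverse_complement(head), None, index, max_look, extension_max_n
            )
            up_ext = reverse_complement(grown.sequence)[: len(grown.sequence) - plen]
        tail = core[-plen:]
        if "X" not in tail and "N" not in tail:
            grown = bridge(tail, None, index, max_look, extension_max_n)
            down_ext = grown.sequence[plen:]

    return BES(
        gene_id=fdm.gene_id,
        sequence=up_ext + core + down_ext,
        bridged_flags=bridged,
        unresolved_flags=unresolved,
        upstream_extension_len=len(up_ext),
        downstream_extension_len=len(down_ext),
    )
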