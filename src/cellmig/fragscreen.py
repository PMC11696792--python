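"""Bookkeeping for an AlphaFold2-Multimer fragment screen.

A long, mostly disordered bait protein is split into overlapping ~100-aa
fragments; each fragment is predicted against candidate partner domains
using species-paired "mixed" co-alignments, and candidates are ranked on
the predictor's confidence scores.  This module implements the
delimitation, MSA filtering/pairing and score-aggregation contracts; the
neural-network predictor itself is an interface (a mock backend reads a
score table, an external backend shells out to a user-supplied command).

Scores follow the AlphaFold2-Multimer conventions: per model, pLDDT
(stored /100), pTM and ipTM in [0, 1]; the model confidence is the 20:80
weighted combination 0.2*pTM + 0.8*ipTM; candidates are ranked by the
average ipTM over the five models and selected when the confidence score
is strictly above the threshold (default 0.65).
"""

from __future__ import annotations

import json
import re
import subprocess
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FragmentScheme",
    "SpeciesMSA",
    "MsaRow",
    "ScoreSet",
    "make_fragments",
    "filter_msa",
    "pair_msas",
    "aggregate_scores",
    "screen",
    "read_a3m",
    "MockPredictor",
    "ExternalPredictor",
]

CONFIDENCE_PTM_WEIGHT = 0.2
CONFIDENCE_IPTM_WEIGHT = 0.8
DEFAULT_THRESHOLD = 0.65


# ---------------------------------------------------------------------------
# Fragment delimitation

@dataclass(frozen=True)
class FragmentScheme:
    """Ordered, overlapping 1-based residue delimitations covering a protein."""

    protein_id: str
    length: int
    fragments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        frags = tuple((int(s), int(e)) for s, e in self.fragments)
        if not frags:
            raise ValueError("no fragments")
        starts = [s for s, _ in frags]
        if any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
            raise ValueError("fragment starts must be strictly increasing")
        for s, e in frags:
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"fragment ({s},{e}) outside [1,{self.length}]")
        if frags[0][0] != 1:
            raise ValueError("fragments must start at residue 1")
        for (s1, e1), (s2, e2) in zip(frags, frags[1:]):
            if s2 > e1 + 1:
                raise ValueError(f"gap between fragments ({s1},{e1}) and ({s2},{e2})")
            if len(frags) > 1 and s2 > e1:
                raise ValueError("consecutive fragments must overlap by >= 1 residue")
        object.__setattr__(self, "fragments", frags)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def covered_end(self) -> int:
        return max(e for _, e in self.fragments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "fragment": np.arange(1, self.n_fragments + 1),
                "start": [s for s, _ in self.fragments],
                "end": [e for _, e in self.fragments],
            }
        )


def make_fragments(
    length: int,
    n_fragments: int | None = None,
    target_len: int = 100,
    min_overlap: int = 20,
    protein_id: str = "protein",
) -> FragmentScheme:
    """Evenly spaced overlapping fragments of ``target_len`` residues.

    Fragment i (1-based) starts at round((i-1)*(length-target_len)/(n-1))+1
    and spans ``target_len`` residues, so the first fragment is (1,
    target_len) and the last ends exactly at ``length``.  When ``n`` is
    omitted, the smallest count giving pairwise overlap >= ``min_overlap``
    is used.
    """
    if length < target_len:
        raise ValueError(f"length {length} shorter than target fragment {target_len}")
    if n_fragments is None:
        if length == target_len:
            n_fragments = 1
        else:
            # step (length-target)/(n-1) <= target - min_overlap
            n_fragments = int(np.ceil((length - target_len) / (target_len - min_overlap))) + 1
    if n_fragments * target_len < length:
        raise ValueError(
            f"cannot cover {length} residues with {n_fragments} fragments of {target_len}"
        )
    if n_fragments == 1:
        if length != target_len:
            raise ValueError("a single fragment cannot overlap-cover length > target_len")
        return FragmentScheme(protein_id, length, ((1, length),))
    step = (length - target_len) / (n_fragments - 1)
    frags = []
    for i in range(1, n_fragments + 1):
        start = int(np.floor((i - 1) * step + 0.5)) + 1
        frags.append((start, start + target_len - 1))
    return FragmentScheme(protein_id, length, tuple(frags))


# ---------------------------------------------------------------------------
# MSAs

@dataclass(frozen=True)
class MsaRow:
    row_id: str
    species: str
    seq: str  # aligned, uppercase, '-' gaps


@dataclass(frozen=True)
class SpeciesMSA:
    """Aligned MSA with species tags; the query is the first row."""

    rows: tuple[MsaRow, ...]

    def __post_init__(self):
        rows = tuple(self.rows)
        if not rows:
            raise ValueError("empty MSA")
        width = len(rows[0].seq)
        if any(len(r.seq) != width for r in rows):
            raise ValueError("aligned rows must share one length")
        object.__setattr__(self, "rows", rows)

    @property
    def query(self) -> MsaRow:
        return self.rows[0]

    @property
    def width(self) -> int:
        return len(self.rows[0].seq)

    @property
    def species_set(self) -> set[str]:
        return {r.species for r in self.rows[1:]}


def _query_stats(query: str, seq: str) -> tuple[float, float]:
    """(identity%, coverage%) of a member row against the query.

    Coverage = fraction of query (non-gap) columns the row covers;
    identity = matches over the query columns the row covers.
    """
    q = np.frombuffer(query.encode(), dtype="S1")
    s = np.frombuffer(seq.encode(), dtype="S1")
    qcols = q != b"-"
    n_q = int(qcols.sum())
    if n_q == 0:
        return 0.0, 0.0
    covered = qcols & (s != b"-")
    n_cov = int(covered.sum())
    cov = 100.0 * n_cov / n_q
    if n_cov == 0:
        return 0.0, cov
    ident = 100.0 * int((q[covered] == s[covered]).sum()) / n_cov
    return ident, cov


def filter_msa(
    msa: SpeciesMSA,
    qid: float = 25.0,
    cov: float = 50.0,
    max_pairwise_id: float = 100.0,
    one_per_species: bool = True,
) -> SpeciesMSA:
    """Filter an MSA the way a fragment screen prepares its inputs.

    Member rows are kept iff identity-to-query >= ``qid``% and coverage >=
    ``cov``%; exact duplicate sequences collapse (``max_pairwise_id`` = 100
    removes only 100%-identical rows); per species only the row with the
    highest identity-to-query survives.  The query is always kept.
    """
    if max_pairwise_id < 100.0:
        raise NotImplementedError("only exact-duplicate removal (id=100) is supported")
    query = msa.query
    scored = []
    seen_seqs = {query.seq}
    for r in msa.rows[1:]:
        ident, coverage = _query_stats(query.seq, r.seq)
        if ident < qid or coverage < cov:
            continue
        if r.seq in seen_seqs:
            continue
        seen_seqs.add(r.seq)
        scored.append((r, ident))
    if one_per_species:
        best: dict[str, tuple[MsaRow, float]] = {}
        order: list[str] = []
        for r, ident in scored:
            if r.species not in best or ident > best[r.species][1]:
                best[r.species] = (r, ident)
            if r.species not in order:
                order.append(r.species)
        kept = [best[sp][0] for sp in order]
    else:
        kept = [r for r, _ in scored]
    return SpeciesMSA(rows=(query, *kept))


def pair_msas(msa_a: SpeciesMSA, msa_b: SpeciesMSA) -> SpeciesMSA:
    """Species-paired mixed co-alignment of two filtered MSAs.

    Row 1 concatenates the two queries.  Each species present in both MSAs
    contributes one concatenated row; a species present in only one MSA is
    kept with the partner block gap-padded.  Total width is the sum of the
    input widths.  Row order: paired species (A's order), then A-only, then
    B-only (B's order).
    """
    wa, wb = msa_a.width, msa_b.width
    gap_a, gap_b = "-" * wa, "-" * wb
    by_sp_a = {r.species: r for r in msa_a.rows[1:]}
    by_sp_b = {r.species: r for r in msa_b.rows[1:]}
    rows = [
        MsaRow(
            row_id=f"{msa_a.query.row_id}+{msa_b.query.row_id}",
            species="query",
            seq=msa_a.query.seq + msa_b.query.seq,
        )
    ]
    for r in msa_a.rows[1:]:
        if r.species in by_sp_b:
            rb = by_sp_b[r.species]
            rows.append(MsaRow(f"{r.row_id}+{rb.row_id}", r.species, r.seq + rb.seq))
    for r in msa_a.rows[1:]:
        if r.species not in by_sp_b:
            rows.append(MsaRow(r.row_id, r.species, r.seq + gap_b))
    for r in msa_b.rows[1:]:
        if r.species not in by_sp_a:
            rows.append(MsaRow(r.row_id, r.species, gap_a + r.seq))
    return SpeciesMSA(rows=tuple(rows))


_DEFAULT_SPECIES_RE = re.compile(r"_([A-Z0-9]{3,})$")


def read_a3m(path, species_regex: str | None = None) -> SpeciesMSA:
    """Read an A3M or aligned-FASTA file into a SpeciesMSA.

    Lowercase letters (A3M insertions relative to the query) are removed;
    the species tag is extracted from each header with ``species_regex``
    (first group), defaulting to the UniProt-style suffix after the last
    underscore (e.g. ``..._HUMAN``).
    """
    pat = re.compile(species_regex) if species_regex else _DEFAULT_SPECIES_RE
    rows = []
    header, chunks = None, []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        seq = "".join(ch for ch in seq if not ch.islower())
        name = header.split()[0]
        m = pat.search(name)
        species = m.group(1) if m else name
        rows.append(MsaRow(row_id=name, species=species, seq=seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line:
                continue
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            else:
                chunks.append(line)
        flush()
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return SpeciesMSA(rows=tuple(rows))


def write_a3m(msa: SpeciesMSA, path) -> None:
    with open(path, "w") as fh:
        for r in msa.rows:
            fh.write(f">{r.row_id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# Scores

@dataclass(frozen=True)
class ScoreSet:
    """Per-model predictor scores for one bait-fragment x prey-domain pair."""

    bait: str
    prey: str
    plddt: tuple[float, ...]
    ptm: tuple[float, ...]
    iptm: tuple[float, ...]

    def __post_init__(self):
        n = len(self.iptm)
        if not (1 <= n <= 5) or len(self.ptm) != n or len(self.plddt) != n:
            raise ValueError("1-5 models, each with plddt, ptm and iptm")
        for name, vals in (("plddt", self.plddt), ("ptm", self.ptm), ("iptm", self.iptm)):
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} scores must lie in [0, 1] (store pLDDT / 100)")

    @property
    def avg_iptm(self) -> float:
        return float(np.mean(self.iptm))

    @property
    def confidence(self) -> tuple[float, ...]:
        return tuple(
            CONFIDENCE_PTM_WEIGHT * p + CONFIDENCE_IPTM_WEIGHT * i
            for p, i in zip(self.ptm, self.iptm)
        )

    @property
    def best_confidence(self) -> float:
        return max(self.confidence)

    @property
    def avg_confidence(self) -> float:
        return float(np.mean(self.confidence))


def aggregate_scores(raw: dict) -> ScoreSet:
    """Build a ScoreSet from a raw record {bait, prey, models:[{plddt,ptm,iptm}]}.

    pLDDT values on the 0-100 scale are accepted and stored divided by 100.
    """
    models = raw["models"]
    plddt = tuple(
        (m["plddt"] / 100.0) if m["plddt"] > 1.0 else float(m["plddt"]) for m in models
    )
    return ScoreSet(
        bait=str(raw["bait"]),
        prey=str(raw["prey"]),
        plddt=plddt,
        ptm=tuple(float(m["ptm"]) for m in models),
        iptm=tuple(float(m["iptm"]) for m in models),
    )


def screen(
    score_sets: Sequence[ScoreSet],
    threshold: float = DEFAULT_THRESHOLD,
    rank_by: str = "avg_iptm",
    select_by: str = "best_confidence",
) -> pd.DataFrame:
    """Rank candidates and keep those strictly above the confidence threshold.

    Selection is on ``select_by`` (default the best per-model confidence)
    with a strict > comparison; ranking is by ``rank_by`` (default the
    average ipTM over models) descending, ties broken by best confidence
    then lexical candidate id.  An empty result is allowed.
    """
    if not score_sets:
        raise ValueError("no score sets")
    rows = []
    for s in score_sets:
        rows.append(
            {
                "bait": s.bait,
                "prey": s.prey,
                "avg_iptm": s.avg_iptm,
                "best_confidence": s.best_confidence,
                "avg_confidence": s.avg_confidence,
            }
        )
    df = pd.DataFrame(rows)
    df["candidate_id"] = df["bait"] + "|" + df["prey"]
    kept = df[df[select_by] > threshold].copy()
    kept = kept.sort_values(
        by=[rank_by, "best_confidence", "candidate_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    kept.insert(0, "rank", np.arange(1, len(kept) + 1))
    return kept


# ---------------------------------------------------------------------------
# Predictor backends

class MockPredictor:
    """Predictor backend that returns scores from a pre-computed table.

    ``table`` maps (bait, prey) to a raw record accepted by
    ``aggregate_scores``; used to exercise the screen bookkeeping without
    running any structure prediction.
    """

    def __init__(self, table: dict[tuple[str, str], dict]):
        self._table = dict(table)

    def predict(self, bait: str, prey: str) -> ScoreSet:
        key = (bait, prey)
        if key not in self._table:
            raise KeyError(f"no mock scores for {key}")
        return aggregate_scores(self._table[key])


class ExternalPredictor:
    """Predictor backend that shells out to a user-supplied command.

    The command receives the bait and prey ids as arguments and must print
    a JSON record {bait, prey, models:[{plddt,ptm,iptm}]} on stdout.  Meant
    for wiring real structure-prediction pipelines in; not exercised in
    automated tests.
    """

    def __init__(self, command: Sequence[str]):
        self.command = list(command)

    def predict(self, bait: str, prey: str) -> ScoreSet:
        proc = subprocess.run(
            [*self.command, bait, prey], capture_output=True, text=True, check=True
        )
        return aggregate_scores(json.loads(proc.stdout))
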