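"""Dictionary-based tagging of clinical note text.

Tags dictionary terms in free-text notes in a NER fashion: tokens are
normalized (lowercase, punctuation stripped, optional lemma-table lookup),
matched against term dictionaries longest-match-first, with single-edit
fuzzy matching for unmatched single tokens, and negation / non-patient
subject suppression within a sentence. Surviving (non-negated) mentions
become dated code events for the downstream phenotype vectors.

Fuzzy matching uses Levenshtein distance <= 1 (substitution, insertion or
deletion), so misspellings like "diabtes" resolve to "diabetes". Tokens of
three characters or fewer never fuzzy-match, as a guard against noise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .containers import MENTION_COLUMNS

# Negation cues ("no sign of retinopathy") and non-patient subject cues
# ("the patient's mother had retinopathy") suppress a mention when they
# occur within DEFAULT_NEGATION_WINDOW tokens before it in the same sentence.
DEFAULT_NEGATION_CUES = frozenset(
    {"no", "not", "without", "denies", "denied", "never", "negative"}
)
DEFAULT_SUBJECT_CUES = frozenset(
    {"mother", "father", "family", "sister", "brother", "parent",
     "grandmother", "grandfather"}
)
DEFAULT_NEGATION_WINDOW = 5

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)?")
_SENT_RE = re.compile(r"[^.!?;]+")
_PUNCT_RE = re.compile(r"[^a-z0-9 ]+")


@dataclass(frozen=True)
class DictionaryEntry:
    """One dictionary row: a normalized surface term mapped to a code."""

    term: str  # normalized, tokens joined by single spaces
    code: str
    vocabulary: str  # "ICD10" or "CUSTOM"

    @property
    def tokens(self) -> tuple:
        return tuple(self.term.split())


def normalize_token(raw: str, lemma_table: Mapping[str, str] | None = None) -> str:
    """Lowercase, strip punctuation, and map through the lemma table.

    Tokens absent from the table are returned unchanged (identity fallback);
    there is no error path.
    """
    tok = _PUNCT_RE.sub("", raw.lower())
    if lemma_table:
        tok = lemma_table.get(tok, tok)
    return tok


def levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Edit distance (substitution/insertion/deletion all cost 1)."""
    if a == b:
        return 0
    if cap is not None and abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev = cur
    return prev[-1]


def read_dictionary(path) -> list[DictionaryEntry]:
    """Read a term dictionary from TSV: term<TAB>code<TAB>vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    df.columns = ["term", "code", "vocabulary"]
    return entries_from_frame(df)


def entries_from_frame(df: pd.DataFrame) -> list[DictionaryEntry]:
    out = []
    seen = set()
    for term, code, vocab in df[["term", "code", "vocabulary"]].itertuples(index=False):
        norm = " ".join(
            t for t in (normalize_token(w) for w in str(term).split()) if t
        )
        if not norm:
            raise ValueError(f"dictionary term {term!r} empty after normalization")
        key = (norm, code, vocab)
        if key in seen:
            continue
        seen.add(key)
        out.append(DictionaryEntry(norm, str(code), str(vocab)))
    return out


class TermIndex:
    """Lookup structure over dictionary entries.

    Exact lookups run over normalized token windows (multi-token terms are
    matched exactly); fuzzy lookups apply to single-token terms only,
    bucketed by length so only terms within one length unit are scanned.
    """

    def __init__(
        self,
        entries: Iterable[DictionaryEntry],
        lemma_table: Mapping[str, str] | None = None,
    ):
        self.lemma_table = dict(lemma_table or {})
        self.exact: dict[tuple, list[DictionaryEntry]] = {}
        self._by_len: dict[int, list[DictionaryEntry]] = {}
        self.max_term_tokens = 1
        for e in entries:
            toks = tuple(
                normalize_token(t, self.lemma_table) for t in e.term.split()
            )
            self.exact.setdefault(toks, []).append(e)
            self.max_term_tokens = max(self.max_term_tokens, len(toks))
            if len(toks) == 1:
                self._by_len.setdefault(len(toks[0]), []).append(e)
        if not self.exact:
            raise ValueError("dictionary is empty")

    def fuzzy(self, token: str, max_edits: int = 1) -> list[DictionaryEntry]:
        if max_edits == 0 or len(token) <= 3:
            return []
        hits = []
        for length in (len(token) - 1, len(token), len(token) + 1):
            for e in self._by_len.get(length, ()):
                if levenshtein(token, e.term, cap=1) <= 1:
                    hits.append(e)
        return hits


def fuzzy_match(
    token: str,
    dictionary: TermIndex | Iterable[DictionaryEntry],
    max_edits: int = 1,
) -> list[tuple[DictionaryEntry, bool]]:
    """Match a normalized token against the dictionary.

    Exact matches are returned preferentially with fuzzy=False; otherwise
    single-token entries within edit distance 1 are returned flagged fuzzy.
    Tokens of length <= 3 never fuzzy-match.
    """
    if max_edits not in (0, 1):
        raise ValueError("max_edits must be 0 or 1")
    index = dictionary if isinstance(dictionary, TermIndex) else TermIndex(dictionary)
    exact = index.exact.get((token,), [])
    if exact:
        return [(e, False) for e in exact]
    return [(e, True) for e in index.fuzzy(token, max_edits)]


def detect_negation(
    sentence_tokens: Sequence[str],
    position: int,
    negation_cues: frozenset = DEFAULT_NEGATION_CUES,
    subject_cues: frozenset = DEFAULT_SUBJECT_CUES,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> bool:
    """True when a negation or non-patient subject cue precedes the mention
    within ``window`` tokens of the same sentence."""
    lo = max(0, position - window)
    cues = negation_cues | subject_cues
    return any(tok in cues for tok in sentence_tokens[lo:position])


def _sentence_tokens(text: str):
    """Yield per-sentence lists of (raw, start, end) token triples."""
    for sent in _SENT_RE.finditer(text):
        toks = [
            (m.group(0), sent.start() + m.start(), sent.start() + m.end())
            for m in _TOKEN_RE.finditer(sent.group(0))
        ]
        if toks:
            yield toks


def tag_note(
    text: str,
    index: TermIndex,
    max_edits: int = 1,
    negation_cues: frozenset = DEFAULT_NEGATION_CUES,
    subject_cues: frozenset = DEFAULT_SUBJECT_CUES,
    window: int = DEFAULT_NEGATION_WINDOW,
    blocklist: set | None = None,
) -> list[dict]:
    """Tag one note, longest-match-first over normalized token windows.

    Duplicate matches of the same code at one locus (e.g. a term present in
    both dictionaries) are collapsed to a single mention. Returns raw
    mention dicts without patient/date context.
    """
    mentions: list[dict] = []
    for toks in _sentence_tokens(text):
        norm = [normalize_token(raw, index.lemma_table) for raw, _, _ in toks]
        i = 0
        n = len(toks)
        while i < n:
            hit: list[tuple[DictionaryEntry, bool]] = []
            span_len = 0
            for L in range(min(index.max_term_tokens, n - i), 0, -1):
                win = tuple(norm[i : i + L])
                if any(not t for t in win):
                    continue
                entries = index.exact.get(win)
                if entries:
                    hit = [(e, False) for e in entries]
                    span_len = L
                    break
                if L == 1:
                    fz = index.fuzzy(win[0], max_edits)
                    if fz:
                        hit = [(e, True) for e in fz]
                        span_len = L
                        break
            if not hit:
                i += 1
                continue
            start = toks[i][1]
            end = toks[i + span_len - 1][2]
            surface = text[start:end]
            matched_norm = " ".join(norm[i : i + span_len])
            negated = detect_negation(norm, i, negation_cues, subject_cues, window)
            seen_codes = set()
            for entry, fuzzy in hit:
                if blocklist and (matched_norm, entry.code) in blocklist:
                    continue
                if entry.code in seen_codes:  # duplicate across vocabularies
                    continue
                seen_codes.add(entry.code)
                mentions.append(
                    {
                        "code": entry.code,
                        "vocabulary": entry.vocabulary,
                        "start": start,
                        "end": end,
                        "matched": surface,
                        "negated": negated,
                        "fuzzy": fuzzy,
                    }
                )
            i += span_len
    return mentions


def tag_corpus(
    notes: pd.DataFrame,
    dictionaries: Iterable[DictionaryEntry] | Sequence[Iterable[DictionaryEntry]],
    lemma_table: Mapping[str, str] | None = None,
    max_edits: int = 1,
    negation_cues: frozenset = DEFAULT_NEGATION_CUES,
    subject_cues: frozenset = DEFAULT_SUBJECT_CUES,
    window: int = DEFAULT_NEGATION_WINDOW,
    blocklist: set | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag every note and derive the mined code-event table.

    Parameters
    ----------
    notes : DataFrame with columns patient_id, date, text.
    dictionaries : entries, or a sequence of entry lists (ICD-10 + custom).
    blocklist : set of (normalized matched surface, code) pairs rejected
        during fuzzy-variant review; matching mentions are dropped.

    Returns
    -------
    mentions : DataFrame (MENTION_COLUMNS) of all mentions incl. negated.
    events : DataFrame (patient_id, code, date, source="mined") from the
        non-negated mentions only.
    """
    entries: list[DictionaryEntry] = []
    seq = list(dictionaries)
    if seq and isinstance(seq[0], DictionaryEntry):
        entries = seq  # type: ignore[assignment]
    else:
        for d in seq:
            entries.extend(d)
    index = TermIndex(entries, lemma_table)
    rows = []
    for patient_id, date, text in notes[["patient_id", "date", "text"]].itertuples(
        index=False
    ):
        if not isinstance(text, str) or not text.strip():
            continue
        for m in tag_note(
            text, index, max_edits, negation_cues, subject_cues, window, blocklist
        ):
            rows.append({"patient_id": patient_id, "date": date, **m})
    mentions = pd.DataFrame(rows, columns=MENTION_COLUMNS)
    kept = mentions.loc[~mentions["negated"]]
    events = pd.DataFrame(
        {
            "patient_id": kept["patient_id"].to_numpy(),
            "code": kept["code"].to_numpy(),
            "date": pd.to_datetime(kept["date"]).to_numpy()
            if len(kept)
            else pd.to_datetime([]),
            "source": "mined",
        }
    )
    return mentions, events


def read_blocklist(path) -> set:
    """Read rejected (variant, code) pairs from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    return {
        (normalize_token(v), c)
        for v, c in df.iloc[:, :2].itertuples(index=False)
    }
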