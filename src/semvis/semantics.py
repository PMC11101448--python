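"""Free-text response cleaning and semantic embedding.

Observers type 1-3 labels per trial.  Cleaning lowercases, removes stopwords,
single characters and numerals, and spell-corrects words the embedding does
not recognize (edit distance <= 2, preferring candidates from a priority
lexicon of visual words); uncorrectable words are dropped.  Every decision is
recorded in an audit log.  Surviving words are embedded and averaged into one
semantic vector per trial, giving each trial equal weight regardless of how
many labels it received.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._stopwords import DEFAULT_STOPWORDS

__all__ = [
    "RawResponse",
    "EmbeddingModel",
    "TrialSemanticVector",
    "clean_responses",
    "embed_trial",
    "binary_trial_vector",
    "validate_participant",
    "nearest_words",
    "singular_plural_equivalent",
]


@dataclass
class RawResponse:
    trial_id: str
    participant_id: str
    labels: list[str]
    stimulus_id: str | None = None

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("a response must carry at least one label")


class EmbeddingModel:
    """Word -> dense vector lookup (GloVe-style); lowercase-keyed.

    Out-of-vocabulary lookups raise ``KeyError`` — they are never silently
    zero-filled.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty embedding")
        dims = {v.shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector shapes: {dims}")
        self._vectors = {w: np.asarray(v, float) for w, v in vectors.items()}
        self.dimension = next(iter(self._vectors.values())).shape[0]

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self._vectors[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in embedding vocabulary") from None

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> list[str]:
        return list(self._vectors)


@dataclass
class TrialSemanticVector:
    trial_id: str
    values: np.ndarray
    n_words: int


@dataclass
class CleanedResponse:
    trial_id: str
    participant_id: str
    words: list[str]
    stimulus_id: str | None = None


@dataclass
class AuditEntry:
    trial_id: str
    word: str
    action: str  # kept | corrected | dropped
    detail: str = ""
    replacement: str | None = None


def _is_numeral(token: str) -> bool:
    if any(ch.isdigit() for ch in token):
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def _edit_distance(a: str, b: str, limit: int) -> int:
    res = edlib.align(a, b, k=limit)
    return res["editDistance"]  # -1 when > limit


def _correct(
    word: str,
    embedding: EmbeddingModel,
    priority_lexicon: frozenset | set,
    max_distance: int,
) -> str | None:
    """Closest in-vocabulary word within ``max_distance`` edits, or None.

    Ties at equal distance prefer priority-lexicon (visual) words, then
    lexicographic order.
    """
    best: tuple[int, int, str] | None = None
    for cand in embedding.vocabulary:
        if abs(len(cand) - len(word)) > max_distance:
            continue
        d = _edit_distance(word, cand, max_distance)
        if d < 0:
            continue
        key = (d, 0 if cand in priority_lexicon else 1, cand)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def clean_responses(
    raw: list[RawResponse],
    embedding: EmbeddingModel,
    priority_lexicon: set[str] | frozenset = frozenset(),
    stopwords: set[str] | frozenset | None = None,
    max_edit_distance: int = 2,
) -> tuple[list[CleanedResponse], list[AuditEntry]]:
    """Clean label strings; returns cleaned responses plus a full audit log.

    Multiword labels recognized whole by the embedding are kept as single
    tokens; otherwise they are split and each part cleaned separately.
    """
    stopwords = DEFAULT_STOPWORDS if stopwords is None else stopwords
    cleaned: list[CleanedResponse] = []
    log: list[AuditEntry] = []
    for resp in raw:
        words: list[str] = []
        for label in resp.labels:
            label = label.strip().lower()
            if not label:
                continue
            tokens = [label] if label in embedding else label.split()
            for tok in tokens:
                entry = _clean_token(
                    tok, resp.trial_id, embedding, priority_lexicon, stopwords,
                    max_edit_distance,
                )
                log.append(entry)
                if entry.action == "kept":
                    words.append(tok)
                elif entry.action == "corrected":
                    words.append(entry.replacement)  # type: ignore[arg-type]
        cleaned.append(
            CleanedResponse(
                trial_id=resp.trial_id,
                participant_id=resp.participant_id,
                words=words,
                stimulus_id=resp.stimulus_id,
            )
        )
    return cleaned, log


def _clean_token(
    tok, trial_id, embedding, priority_lexicon, stopwords, max_edit_distance
) -> AuditEntry:
    if tok in stopwords:
        return AuditEntry(trial_id, tok, "dropped", "stopword")
    if len(tok) == 1:
        return AuditEntry(trial_id, tok, "dropped", "single character")
    if _is_numeral(tok):
        return AuditEntry(trial_id, tok, "dropped", "numeral")
    if tok in embedding:
        return AuditEntry(trial_id, tok, "kept")
    fixed = _correct(tok, embedding, priority_lexicon, max_edit_distance)
    if fixed is not None and fixed not in stopwords:
        return AuditEntry(
            trial_id, tok, "corrected", f"edit distance <= {max_edit_distance}", fixed
        )
    return AuditEntry(trial_id, tok, "dropped", "uncorrectable / out of vocabulary")


def embed_trial(words: list[str], embedding: EmbeddingModel) -> np.ndarray:
    """Arithmetic mean of the word vectors (equal weight per word)."""
    if not words:
        raise ValueError("cannot embed an empty word list")
    return np.mean([embedding[w] for w in words], axis=0)


def trial_semantic_vectors(
    cleaned: list[CleanedResponse], embedding: EmbeddingModel
) -> tuple[list[TrialSemanticVector], list[str]]:
    """One mean vector per trial; trials with no surviving word are flagged."""
    out, invalid = [], []
    for resp in cleaned:
        if resp.words:
            out.append(
                TrialSemanticVector(
                    resp.trial_id, embed_trial(resp.words, embedding), len(resp.words)
                )
            )
        else:
            invalid.append(resp.trial_id)
    return out, invalid


def binary_trial_vector(words: list[str], vocab: list[str]) -> np.ndarray:
    """0/1 indicator of which vocab words appear among the trial's words."""
    if not vocab:
        raise ValueError("vocab must be non-empty")
    present = set(words)
    return np.array([1.0 if w in present else 0.0 for w in vocab])


def validate_participant(
    words: list[str],
    concreteness: dict[str, float],
    threshold_rating: float = 4.0,
    threshold_frac: float = 0.25,
) -> tuple[bool, float]:
    """Keep/exclude a participant by the low-concreteness fraction rule.

    Excluded iff the fraction of rated words with concreteness below
    ``threshold_rating`` strictly exceeds ``threshold_frac``.  Unrated words
    are ignored in the fraction.  Returns (keep, fraction).
    """
    rated = [w for w in words if w in concreteness]
    if not rated:
        return True, 0.0
    frac = sum(concreteness[w] < threshold_rating for w in rated) / len(rated)
    return frac <= threshold_frac, frac


def nearest_words(
    vector: np.ndarray,
    embedding: EmbeddingModel,
    lexicon: list[str] | set[str],
    k: int = 5,
) -> list[tuple[str, float]]:
    """Top-k lexicon words by cosine similarity to ``vector``.

    Ties break lexicographically; returns (word, cosine) pairs, best first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lex = sorted(lexicon)
    if not lex:
        raise ValueError("empty lexicon")
    v = np.asarray(vector, float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero-norm query vector")
    sims = []
    for w in lex:
        e = embedding[w]
        sims.append((float(v @ e / (nv * np.linalg.norm(e))), w))
    # descending similarity, ascending word for ties
    order = sorted(sims, key=lambda p: (-p[0], p[1]))
    return [(w, s) for s, w in order[:k]]


def singular_plural_equivalent(a: str, b: str, embedding: EmbeddingModel | None = None) -> bool:
    """True when a and b differ only by a trailing plural 's'.

    When an embedding is given, the stripped form must be in its vocabulary
    (a guard against stripping non-plural trailing s).  This deliberately
    falls short of full lemmatization.
    """
    if a == b:
        return True
    for x, y in ((a, b), (b, a)):
        if x == y + "s" and (embedding is None or y in embedding):
            return True
    return False
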