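"""Connectionist temporal classification: greedy decoding and loss.

The alphabet is fixed: class 0 is the CTC blank, classes 1..4 are A, C, G
and T. Greedy (best-path) decoding takes the per-position argmax, collapses
consecutive repeats and deletes blanks. The loss is the standard
forward-backward recursion over the extended label sequence
(blank, l1, blank, l2, ..., blank); its gradient with respect to the
pre-softmax logits is ``softmax - gamma`` where gamma is the per-frame
state posterior collapsed onto classes.

Two interchangeable loss implementations are provided: a vectorized
log-space reference in plain NumPy, and a per-read scaled linear-space
kernel JIT-compiled with numba when available (the recursions are
inherently sequential in time, where a compiled loop is much faster). The
test suite asserts their agreement.
"""

from __future__ import annotations

import numpy as np

try:  # optional JIT for the forward-backward recursions
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # pragma: no cover
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

BLANK = 0
ALPHABET = "ACGT"
N_CLASSES = 5

_NEG_INF = -np.inf


def labels_to_classes(seq: str) -> np.ndarray:
    """Map a nucleotide string to CTC classes 1..4."""
    lut = {b: i + 1 for i, b in enumerate(ALPHABET)}
    try:
        return np.array([lut[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGT label {e.args[0]!r}") from None


def collapse_path(path: np.ndarray) -> str:
    """CTC collapse: merge consecutive repeats, then drop blanks."""
    path = np.asarray(path, dtype=np.int64)
    if path.size == 0:
        return ""
    keep = np.ones(path.size, dtype=bool)
    keep[1:] = path[1:] != path[:-1]
    merged = path[keep]
    merged = merged[merged != BLANK]
    return "".join(ALPHABET[c - 1] for c in merged)


def ctc_greedy_decode(log_probs: np.ndarray,
                      valid_positions: int | None = None) -> str:
    """Best-path decode of a (positions x 5) log-probability matrix.

    Argmax ties break to the lowest class index (the blank wins ties with
    bases), making the decode deterministic.
    """
    lp = np.asarray(log_probs)
    if lp.ndim != 2 or lp.shape[1] != N_CLASSES:
        raise ValueError(f"expected a (positions, {N_CLASSES}) matrix, got {lp.shape}")
    if valid_positions is None:
        valid_positions = lp.shape[0]
    if valid_positions > lp.shape[0]:
        raise ValueError("valid_positions exceeds the number of rows")
    path = np.argmax(lp[:valid_positions], axis=1)
    return collapse_path(path)


def min_path_frames(classes: np.ndarray) -> int:
    """Minimum number of frames a label sequence can be emitted in."""
    if classes.size == 0:
        return 0
    repeats = int(np.sum(classes[1:] == classes[:-1]))
    return int(classes.size + repeats)


def _extend(classes: np.ndarray) -> np.ndarray:
    ext = np.full(2 * classes.size + 1, BLANK, dtype=np.int64)
    ext[1::2] = classes
    return ext


def ctc_loss_batch(
    log_probs: np.ndarray,
    input_lengths: np.ndarray,
    label_list: list[np.ndarray],
    impl: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Loss and gradient for a batch of chunks.

    Parameters
    ----------
    log_probs
        ``(B, T, 5)`` log-probabilities (already log-softmaxed).
    input_lengths
        per-chunk number of valid frames.
    label_list
        per-chunk class sequences (values in 1..4).
    impl
        ``"numba"``, ``"reference"`` or ``"auto"`` (JIT kernel when
        available).

    Returns
    -------
    losses : ``(B,)`` negative log-likelihoods (``inf`` when no valid
        alignment exists, e.g. too few frames).
    grad_logits : ``(B, T, 5)`` gradient of the summed loss with respect to
        the pre-softmax logits (``softmax - gamma``); rows beyond a chunk's
        valid length are zero, as are rows of infeasible chunks.
    """
    if impl == "auto":
        impl = "numba" if _HAVE_NUMBA else "reference"
    if impl == "numba":
        if not _HAVE_NUMBA:
            raise RuntimeError("numba is not available")
        return _ctc_loss_numba(log_probs, input_lengths, label_list)
    if impl == "reference":
        return _ctc_loss_reference(log_probs, input_lengths, label_list)
    raise ValueError(f"unknown impl {impl!r}")


# ---------------------------------------------------------------------------
# scaled linear-space kernel (per read), JIT-compiled
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ctc_single(probs, t_len, ext, skip_ok, grad_out):  # pragma: no cover
    """One chunk: returns the NLL and adds ``p - gamma`` into grad_out.

    ``probs`` is (T, 5) linear-space probabilities; alpha/beta are
    rescaled per frame so everything stays in float64 range, and per-frame
    posteriors are normalised directly.
    """
    s_len = ext.shape[0]
    alpha = np.zeros((t_len, s_len))
    # init
    alpha[0, 0] = probs[0, ext[0]]
    if s_len > 1:
        alpha[0, 1] = probs[0, ext[1]]
    loglik = 0.0
    c0 = alpha[0].sum()
    if c0 <= 0.0:
        return np.inf
    alpha[0] /= c0
    loglik += np.log(c0)
    for t in range(1, t_len):
        prev = alpha[t - 1]
        cur = alpha[t]
        for s in range(s_len):
            a = prev[s]
            if s >= 1:
                a += prev[s - 1]
            if s >= 2 and skip_ok[s]:
                a += prev[s - 2]
            cur[s] = a * probs[t, ext[s]]
        c = cur.sum()
        if c <= 0.0:
            return np.inf
        for s in range(s_len):
            cur[s] /= c
        loglik += np.log(c)
    tail = alpha[t_len - 1, s_len - 1]
    if s_len > 1:
        tail += alpha[t_len - 1, s_len - 2]
    if tail <= 0.0:
        return np.inf
    loglik += np.log(tail)

    # backward + posterior; beta_t(s) excludes the emission at frame t
    beta = np.zeros(s_len)
    beta[s_len - 1] = 1.0
    if s_len > 1:
        beta[s_len - 2] = 1.0
    new_beta = np.zeros(s_len)
    for t in range(t_len - 1, -1, -1):
        # posterior at frame t, normalised per frame
        norm = 0.0
        for s in range(s_len):
            norm += alpha[t, s] * beta[s]
        if norm > 0.0:
            for s in range(s_len):
                post = alpha[t, s] * beta[s] / norm
                grad_out[t, ext[s]] -= post
        if t > 0:
            for s in range(s_len):
                v = beta[s] * probs[t, ext[s]]
                if s + 1 < s_len:
                    v += beta[s + 1] * probs[t, ext[s + 1]]
                if s + 2 < s_len and skip_ok[s + 2]:
                    v += beta[s + 2] * probs[t, ext[s + 2]]
                new_beta[s] = v
            c = new_beta.max()
            if c <= 0.0:
                return np.inf
            for s in range(s_len):
                beta[s] = new_beta[s] / c
    return -loglik


def _ctc_loss_numba(log_probs, input_lengths, label_list):
    lp = np.ascontiguousarray(log_probs, dtype=np.float64)
    b, t_max, _ = lp.shape
    input_lengths = np.asarray(input_lengths, dtype=np.int64)
    probs = np.exp(lp)
    losses = np.empty(b)
    grad = probs.copy()
    for i, lab in enumerate(label_list):
        lab = np.asarray(lab, dtype=np.int64)
        t_len = int(input_lengths[i])
        grad[i, t_len:, :] = 0.0
        if min_path_frames(lab) > t_len:
            losses[i] = np.inf
            grad[i] = 0.0
            continue
        ext = _extend(lab)
        skip_ok = np.zeros(ext.size, dtype=np.bool_)
        if lab.size > 1:
            skip_ok[3::2] = lab[1:] != lab[:-1]
        losses[i] = _ctc_single(probs[i], t_len, ext, skip_ok, grad[i])
        if not np.isfinite(losses[i]):
            grad[i] = 0.0
    return losses, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# vectorized log-space reference
# ---------------------------------------------------------------------------

def _ctc_loss_reference(log_probs, input_lengths, label_list):
    lp = np.asarray(log_probs, dtype=np.float64)
    b, t_max, n_cls = lp.shape
    assert n_cls == N_CLASSES
    input_lengths = np.asarray(input_lengths, dtype=np.int64)

    s_max = max((2 * len(l) + 1) for l in label_list)
    ext = np.zeros((b, s_max), dtype=np.int64)
    s_len = np.zeros(b, dtype=np.int64)
    skip_ok = np.zeros((b, s_max), dtype=bool)
    feasible = np.ones(b, dtype=bool)
    for i, lab in enumerate(label_list):
        lab_arr = np.asarray(lab, dtype=np.int64)
        e = _extend(lab_arr)
        ext[i, : e.size] = e
        s_len[i] = e.size
        if lab_arr.size > 1:
            # skip transition s-2 -> s allowed into label states whose
            # label differs from the one two states back
            skip_ok[i, 3 : e.size : 2] = lab_arr[1:] != lab_arr[:-1]
        if min_path_frames(lab_arr) > input_lengths[i]:
            feasible[i] = False
    pad_state = np.arange(s_max)[None, :] >= s_len[:, None]

    # per-frame emission log-probs of every extended state: (B, T, S)
    emit = np.take_along_axis(lp, ext[:, None, :], axis=2)
    emit[np.broadcast_to(pad_state[:, None, :], emit.shape)] = _NEG_INF

    with np.errstate(divide="ignore", invalid="ignore"):
        alphas = np.full((t_max + 1, b, s_max), _NEG_INF)
        alpha = np.full((b, s_max), _NEG_INF)
        alpha[:, 0] = lp[:, 0, BLANK]
        has1 = s_len > 1
        alpha[has1, 1] = emit[has1, 0, 1]
        alphas[1] = alpha
        shifted1 = np.full((b, s_max), _NEG_INF)
        shifted2 = np.full((b, s_max), _NEG_INF)
        for t in range(1, t_max):
            shifted1[:, 1:] = alpha[:, :-1]
            shifted2[:, 2:] = np.where(skip_ok[:, 2:], alpha[:, :-2], _NEG_INF)
            new_alpha = np.logaddexp(np.logaddexp(alpha, shifted1), shifted2) \
                + emit[:, t, :]
            active = (t < input_lengths)[:, None]
            alpha = np.where(active, new_alpha, alpha)
            alphas[t + 1] = alpha

        rows = np.arange(b)
        a_final = alphas[input_lengths, rows, :]
        ll = a_final[rows, s_len - 1]
        two = s_len > 1
        ll[two] = np.logaddexp(ll[two], a_final[rows[two], s_len[two] - 2])

        # backward: betas[t] holds beta_t (suffix probability given the
        # state at t, excluding the emission at t)
        betas = np.full((t_max, b, s_max), _NEG_INF)
        beta = np.full((b, s_max), _NEG_INF)
        last_t = input_lengths - 1
        for t in range(t_max - 1, -1, -1):
            starting = t == last_t
            if starting.any():
                idx = np.where(starting)[0]
                beta[idx] = _NEG_INF
                beta[idx, s_len[idx] - 1] = 0.0
                two_i = idx[s_len[idx] > 1]
                beta[two_i, s_len[two_i] - 2] = 0.0
            betas[t] = beta
            if t > 0:
                em = emit[:, t, :]
                stay = beta + em
                shifted1[:, :-1] = beta[:, 1:] + em[:, 1:]
                shifted1[:, -1] = _NEG_INF
                shifted2[:, :-2] = np.where(skip_ok[:, 2:],
                                            beta[:, 2:] + em[:, 2:], _NEG_INF)
                shifted2[:, -2:] = _NEG_INF
                new_beta = np.logaddexp(np.logaddexp(stay, shifted1), shifted2)
                upd = (t <= last_t)[:, None]
                beta = np.where(upd, new_beta, beta)

        # posteriors and gradient, vectorized over frames
        post = alphas[1:] + betas - ll[None, :, None]  # (T, B, S)
        post = np.exp(post, where=np.isfinite(post), out=np.zeros_like(post))
        frame_valid = np.arange(t_max)[:, None] < input_lengths[None, :]
        post *= frame_valid[:, :, None]
        post[:, ~feasible, :] = 0.0
        onehot = ext[:, :, None] == np.arange(N_CLASSES)[None, None, :]
        onehot = onehot & ~pad_state[:, :, None]
        gamma = np.einsum("tbs,bsc->btc", post, onehot, optimize=True)
        grad = np.exp(lp) - gamma
        grad *= frame_valid.T[:, :, None]
        grad[~feasible] = 0.0

    losses = -ll
    losses[~feasible] = np.inf
    return losses, grad.astype(np.float32)
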