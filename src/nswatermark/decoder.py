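"""Two-level watermark decoder: drift HMM + iterative q-ary LDPC.

Level one treats the subread as the output of an insertion/deletion/
substitution channel and tracks the *drift* (received minus transmitted
position) with a banded HMM lattice. Synchronization is trained on the
known anchor: the subread and templates are reversed and a forward pass
first walks "upstream" along the anchor (pad-CS-A-primer), concentrating
the drift posterior at the barcode boundary; a forward-backward sweep
then scores every u-nt dictionary block, yielding an n x q matrix of
symbol likelihoods P(r | d_i = a). The watermark is removed inside the
emission model by ⊕-shifting dictionary entries per position, so the
lattice itself is watermark-agnostic.

Level two runs sum-product belief propagation on the q-ary parity-check
matrix (flooding schedule); only syndrome-zero outputs count as decoded.
An exhaustive maximum-a-posteriori decoder over all q^k codewords is
provided as an oracle.

The decoding confidence is L = prod_i L(d_i), the product over symbol
positions of the (row-normalized) likelihood of the decoded symbol,
reported in log10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelParams
from .code import BarcodeSpec, LDPCCode

__all__ = [
    "DriftModel",
    "SymbolPosteriors",
    "DecodeResult",
    "WatermarkDecoder",
    "symbol_likelihoods",
    "ldpc_decode",
    "map_decode_exhaustive",
    "decode_subread",
]

_RATE_FLOOR = 1e-4  # keeps the lattice connected at nominally zero rates


@dataclass(frozen=True)
class DriftModel:
    """Banded drift lattice parameters.

    ``max_drift`` bounds |received - transmitted| position; +-15 covers
    more than 3 sigma of the indel random walk over a 117-nt window at
    the default rates, and matches the 25-nt slack the -61 window leaves
    upstream of the 36-nt barcode. ``max_insert_run`` caps insertions
    per lattice step.
    """

    channel: ChannelParams = field(default_factory=ChannelParams)
    max_drift: int = 15
    max_insert_run: int = 2

    def __post_init__(self) -> None:
        if self.max_drift < 1 or self.max_insert_run < 1:
            raise ValueError("max_drift and max_insert_run must be positive")


@dataclass(frozen=True)
class SymbolPosteriors:
    """Row-normalized n x q likelihood matrix, entry (i, a) ∝ P(r | d_i = a);
    ``log10_norms`` holds the per-row normalization constants."""

    likelihoods: np.ndarray
    log10_norms: np.ndarray

    def __post_init__(self) -> None:
        lk = self.likelihoods
        if (lk < 0).any():
            raise ValueError("likelihoods must be nonnegative")
        if not np.allclose(lk.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("likelihood rows must be normalized")


@dataclass(frozen=True)
class DecodeResult:
    status: str  # "decoded" | "failed"
    barcode_id: int | None = None
    codeword: np.ndarray | None = None
    log10_confidence: float | None = None
    is_negative_control: bool = False


class WatermarkDecoder:
    """Precomputed decoder for one (spec, anchor, channel) combination.

    ``anchor_offset_from_end`` is the distance from the subread 3' end
    to the anchor start (56 under the -61/+56 extraction window); the
    36-nt barcode sits immediately upstream of that point.
    """

    def __init__(
        self,
        spec: BarcodeSpec,
        anchor_template: str,
        channel: ChannelParams,
        drift: DriftModel | None = None,
        anchor_offset_from_end: int = 56,
    ):
        self.spec = spec
        self.anchor_template = anchor_template
        self.drift = drift or DriftModel(channel=channel)
        self.channel = channel
        self.offset_end = anchor_offset_from_end
        p = spec.params
        self.n, self.q, self.u, self.l = p.n, p.q, p.u, p.l
        ps = max(channel.P_s, _RATE_FLOOR)
        pi = max(channel.P_i, _RATE_FLOOR)
        pd_ = max(channel.P_d, _RATE_FLOOR)
        self._pi, self._pd = pi, pd_
        nt = spec.nt_map
        # per-char emission rows over observed base, sentinel column = 0
        # (out-of-window positions kill a path)
        em_char = np.full((4, 5), ps / 3.0)
        em_char[np.arange(4), np.arange(4)] = 1.0 - ps
        em_char[:, 4] = 0.0
        anchor_codes = nt.encode(anchor_template)
        A = len(anchor_codes)
        self.A = A
        wm = nt.encode(spec.watermark)
        dict_codes = np.stack([nt.encode(e) for e in spec.dictionary.entries])  # (q,u)
        # reversed-traversal templates -----------------------------------
        # step t in [0, A): anchor base A-1-t; step A+6s+tau: barcode block
        # i = n-1-s, in-word column j = u-1-tau, forward position p = i*u+j.
        T = A + self.l
        em_marg = np.empty((T, 5))
        em_marg[:A] = em_char[anchor_codes[::-1]]
        # marginal emission over a uniform symbol prior at barcode steps
        colfreq = np.stack(
            [np.bincount(dict_codes[:, j], minlength=4) / p.q for j in range(p.u)]
        )  # (u, 4) distribution of dictionary letters per column
        for s in range(self.n):
            i = self.n - 1 - s
            for tau in range(self.u):
                j = self.u - 1 - tau
                pos = i * self.u + j
                dist = colfreq[j][np.arange(4) ^ int(wm[pos])]  # ⊕-shift by watermark
                row = np.empty(5)
                row[:4] = ps / 3.0 + dist * (1.0 - ps - ps / 3.0)
                row[4] = 0.0
                em_marg[A + s * self.u + tau] = row
        self._em_marg = em_marg
        # per-block, per-symbol emission tables: (n_blocks, u_steps, q, 5)
        blocks = np.empty((self.n, self.u, p.q, 5))
        for s in range(self.n):
            i = self.n - 1 - s
            for tau in range(self.u):
                j = self.u - 1 - tau
                chars = dict_codes[:, j] ^ int(wm[i * self.u + j])  # (q,)
                blocks[s, tau] = em_char[chars]
        self._em_blocks = blocks
        self._nt = nt
        D = self.drift.max_drift
        self.min_window = max(self.offset_end, A) + self.l - D
        self._geom_cache: dict = {}

    # -- lattice ----------------------------------------------------------

    def _geometry(self, W: int):
        """Window-length-dependent tables, cached: extended observed-code
        index matrix (sentinel index W for out-of-window) and per-step
        deletion/transmission weights with insertion-run likelihoods and
        channel constants folded in."""
        cached = self._geom_cache.get(W)
        if cached is not None:
            return cached
        D = self.drift.max_drift
        J = self.drift.max_insert_run
        B = 2 * D + 1
        T = self.A + self.l
        e0 = self.offset_end - self.A
        idx = e0 + np.arange(T)[:, None] - D + np.arange(B + J)[None, :]
        valid = (idx >= 0) & (idx < W)
        ext = np.where(valid, np.clip(idx, 0, W - 1), W)
        # w[t, j, b] = P_i^j (1-P_i) (1/4)^j * validity of the j consumed bases
        vf = valid.astype(float)
        wj = np.empty((T, J + 1, B))
        run = np.ones((T, B + J))
        wj[:, 0, :] = 1.0 - self._pi
        for j in range(1, J + 1):
            run[:, : B + J - (j - 1)] *= vf[:, j - 1 :]
            wj[:, j, :] = (self._pi**j) * (1.0 - self._pi) * (0.25**j) * run[:, :B]
        wdel = wj * self._pd
        wtr = wj * (1.0 - self._pd)
        if len(self._geom_cache) > 16:
            self._geom_cache.clear()
        self._geom_cache[W] = (ext, wdel, wtr)
        return ext, wdel, wtr

    def _step(self, alpha: np.ndarray, em5: np.ndarray, codes_ext: np.ndarray,
              wdel: np.ndarray, wtr: np.ndarray) -> np.ndarray:
        """One forward lattice step.

        ``alpha``: (..., B) band vector; ``em5``: (..., 5) emission row(s);
        ``codes_ext``: (B + J,) observed codes at band+run positions with
        sentinel 4 for out-of-window; ``wdel``/``wtr``: (J+1, B) deletion/
        transmission weights from :meth:`_geometry`.
        """
        J = self.drift.max_insert_run
        B = alpha.shape[-1]
        out = np.zeros_like(alpha)
        for j in range(J + 1):
            em_tr = em5[..., codes_ext[j : j + B]]  # (..., B)
            contrib_del = alpha * wdel[j]
            contrib_tr = alpha * (wtr[j] * em_tr)
            # delete: d' = d + j - 1 ; transmit: d' = d + j
            if j == 0:
                out[..., :-1] += contrib_del[..., 1:]
                out += contrib_tr
            else:
                sd = j - 1
                out[..., sd:] += contrib_del[..., : B - sd] if sd else contrib_del
                out[..., j:] += contrib_tr[..., : B - j]
        return out

    def _step_back(self, beta: np.ndarray, em5: np.ndarray, codes_ext: np.ndarray,
                   wdel: np.ndarray, wtr: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`_step`: one backward recurrence step."""
        J = self.drift.max_insert_run
        B = beta.shape[-1]
        out = np.zeros_like(beta)
        pad = np.zeros(beta.shape[:-1] + (J + 1,))
        beta_pad = np.concatenate([beta, pad], axis=-1)
        for j in range(J + 1):
            em_tr = em5[..., codes_ext[j : j + B]]
            b_del = (
                beta_pad[..., j - 1 : j - 1 + B]
                if j >= 1
                else np.concatenate([np.zeros(beta.shape[:-1] + (1,)), beta[..., : B - 1]], axis=-1)
            )
            b_tr = beta_pad[..., j : j + B]
            out += wdel[j] * b_del + (wtr[j] * em_tr) * b_tr
        return out

    def _run(self, window: str):
        D = self.drift.max_drift
        B = 2 * D + 1
        W = len(window)
        if W < self.min_window:
            raise ValueError(
                f"window of {W} nt is below the decodable minimum {self.min_window}"
            )
        codes = self._nt.encode(window)[::-1].astype(np.int64)
        T = self.A + self.l
        ext, wdel, wtr = self._geometry(W)
        codes_pad = np.concatenate([codes, [4]])
        codes_ext = codes_pad[ext]  # (T, B+J)
        # forward marginal pass, storing band vectors at block boundaries
        alpha = np.ones(B) / B
        alpha_bounds = {}
        for t in range(T):
            if t >= self.A and (t - self.A) % self.u == 0:
                alpha_bounds[(t - self.A) // self.u] = alpha.copy()
            alpha = self._step(alpha, self._em_marg[t], codes_ext[t], wdel[t], wtr[t])
            s = alpha.sum()
            if s > 0:
                alpha /= s
        # backward pass from the template end down to the anchor boundary
        beta = np.ones(B)
        beta_bounds = {self.n: beta.copy()}
        for t in range(T - 1, self.A - 1, -1):
            beta = self._step_back(beta, self._em_marg[t], codes_ext[t], wdel[t], wtr[t])
            s = beta.sum()
            if s > 0:
                beta /= s
            rel = t - self.A
            if rel % self.u == 0:
                beta_bounds[rel // self.u] = beta.copy()
        # per-block symbol likelihoods
        q = self.q
        lk = np.zeros((self.n, q))
        for s in range(self.n):
            a_blk = np.broadcast_to(alpha_bounds[s], (q, B)).copy()
            for tau in range(self.u):
                t = self.A + s * self.u + tau
                a_blk = self._step(
                    a_blk, self._em_blocks[s, tau], codes_ext[t], wdel[t], wtr[t]
                )
                m = a_blk.max()
                if m > 0:
                    a_blk /= m  # common scale keeps cross-symbol ratios
            i = self.n - 1 - s  # forward symbol position
            lk[i] = a_blk @ beta_bounds[s + 1]
        norms = lk.sum(axis=1)
        dead = norms <= 0
        lk[dead] = 1.0 / q
        norms[dead] = 1.0
        lk = lk / norms[:, None]
        with np.errstate(divide="ignore"):
            log10_norms = np.where(dead, -np.inf, np.log10(norms))
        return SymbolPosteriors(likelihoods=lk, log10_norms=log10_norms)

    def symbol_likelihoods(self, window: str) -> SymbolPosteriors:
        return self._run(window)

    def decode(
        self, window: str, negative_control_ids: frozenset | set | None = None
    ) -> DecodeResult:
        post = self._run(window)
        cw, _ = ldpc_decode(post, self.spec.code)
        if cw is None:
            return DecodeResult(status="failed")
        payload = cw[self.spec.params.m :]
        bid = self.spec.payload_to_id(payload)
        with np.errstate(divide="ignore"):
            conf = float(
                np.log10(post.likelihoods[np.arange(self.n), cw]).sum()
            )
        return DecodeResult(
            status="decoded",
            barcode_id=bid,
            codeword=cw,
            log10_confidence=conf,
            is_negative_control=bool(
                negative_control_ids and bid in negative_control_ids
            ),
        )


# -- module-level wrappers with a small decoder cache ----------------------

_DECODER_CACHE: dict = {}


def _get_decoder(
    spec: BarcodeSpec,
    anchor_template: str,
    channel: ChannelParams,
    drift: DriftModel | None = None,
    anchor_offset_from_end: int = 56,
) -> WatermarkDecoder:
    key = (
        id(spec),
        anchor_template,
        channel,
        drift,
        anchor_offset_from_end,
    )
    dec = _DECODER_CACHE.get(key)
    if dec is None:
        if len(_DECODER_CACHE) > 64:
            _DECODER_CACHE.clear()
        dec = WatermarkDecoder(
            spec, anchor_template, channel, drift, anchor_offset_from_end
        )
        _DECODER_CACHE[key] = dec
    return dec


def symbol_likelihoods(
    window: str,
    spec: BarcodeSpec,
    anchor_template: str,
    drift: DriftModel,
    anchor_offset_from_end: int = 56,
) -> SymbolPosteriors:
    """Drift-lattice forward-backward symbol likelihoods for one window."""
    dec = _get_decoder(
        spec, anchor_template, drift.channel, drift, anchor_offset_from_end
    )
    return dec.symbol_likelihoods(window)


def decode_subread(
    subread: str,
    spec: BarcodeSpec,
    anchor_template: str,
    channel: ChannelParams,
    drift: DriftModel | None = None,
    negative_control_ids: frozenset | set | None = None,
    anchor_offset_from_end: int = 56,
) -> DecodeResult:
    """Full two-level decode of one forward-oriented subread."""
    dec = _get_decoder(spec, anchor_template, channel, drift, anchor_offset_from_end)
    return dec.decode(subread, negative_control_ids)


# -- q-ary belief propagation ---------------------------------------------


def ldpc_decode(
    posteriors: SymbolPosteriors, code: LDPCCode, max_iter: int = 50
) -> tuple[np.ndarray | None, int]:
    """Sum-product decoding on the parity-check graph (flooding schedule).

    Returns ``(codeword, iterations)`` once the hard decision satisfies
    every check, or ``(None, max_iter)`` if the syndrome is never zero.
    Hard-decision ties break toward the lowest symbol value.
    """
    prior = np.asarray(posteriors.likelihoods, dtype=float)
    p = code.params
    if prior.shape != (p.n, p.q):
        raise ValueError(f"posteriors must be {p.n}x{p.q}, got {prior.shape}")
    q = p.q
    gf = code.gf
    xor_idx = np.arange(q)[:, None] ^ np.arange(q)[None, :]
    edges = [(r, j, int(code.H[r, j])) for r in range(p.m) for j in range(p.n)
             if code.H[r, j]]
    by_check: dict[int, list[int]] = {}
    by_var: dict[int, list[int]] = {}
    for e, (r, j, _) in enumerate(edges):
        by_check.setdefault(r, []).append(e)
        by_var.setdefault(j, []).append(e)
    mul = gf.mul_table
    m_vc = np.stack([prior[j] for _, j, _ in edges])
    m_cv = np.full((len(edges), q), 1.0 / q)

    def hard_decision() -> np.ndarray:
        belief = prior.copy()
        for e, (_, j, _) in enumerate(edges):
            belief[j] *= m_cv[e]
        return belief.argmax(axis=1)

    for it in range(1, max_iter + 1):
        # check-node update
        for r, es in by_check.items():
            transformed = []
            for e in es:
                h = edges[e][2]
                t = np.zeros(q)
                t[mul[h]] = m_vc[e]  # distribution of h·x
                transformed.append(t)
            for pos, e in enumerate(es):
                conv = None
                for pos2, t in enumerate(transformed):
                    if pos2 == pos:
                        continue
                    conv = t if conv is None else conv @ t[xor_idx]
                h = edges[e][2]
                out = conv[mul[h]]  # P(x_e = a) = conv at h·a
                s = out.sum()
                m_cv[e] = out / s if s > 0 else 1.0 / q
        # variable-node update
        for j, es in by_var.items():
            for e in es:
                msg = prior[j].copy()
                for e2 in es:
                    if e2 != e:
                        msg *= m_cv[e2]
                s = msg.sum()
                m_vc[e] = msg / s if s > 0 else 1.0 / q
        cw = hard_decision()
        if not code.syndrome(cw).any():
            return cw.astype(np.int64), it
    return None, max_iter


def map_decode_exhaustive(
    posteriors: SymbolPosteriors, code: LDPCCode
) -> np.ndarray:
    """Exhaustive maximum-a-posteriori decoding over all q^k codewords.

    Maximizes prod_i P(r | d_i = c_i); feasible because the default set
    has only 4096 codewords. Ties break toward the lowest payload id.
    """
    table = code.codeword_table()
    with np.errstate(divide="ignore"):
        logp = np.log(np.asarray(posteriors.likelihoods, dtype=float))
    scores = logp[np.arange(code.params.n), table].sum(axis=1)
    return table[int(scores.argmax())].copy()
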