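"""In-process simulation of a decentralized consortium.

Sites hold private subject data that must never cross the message channel;
all inter-site traffic flows through :class:`Channel`, which enforces a
statistics-only whitelist and logs every transfer so that the total
communication volume of a run can be reconstructed and audited.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Dict, Iterable, List, Optional, Sequence

import numpy as np

__all__ = [
    "SubjectMatrix",
    "SiteState",
    "Message",
    "Channel",
    "Consortium",
    "PrivacyViolation",
    "MESSAGE_WHITELIST",
    "build_consortium",
    "privacy_audit",
]

#: Message kinds that may legally cross the channel.  Raw subject data is
#: not representable: there is no kind for it and ``SubjectMatrix`` payloads
#: are rejected outright.
MESSAGE_WHITELIST = frozenset(
    {"eigen_package", "unmixing_maps", "centroids", "gradients", "counts", "scalar_stats"}
)


class PrivacyViolation(RuntimeError):
    """Raised when something other than whitelisted statistics is sent."""


class SubjectMatrix:
    """One subject's voxels x timepoints data.

    The only object in the system forbidden from crossing the channel.
    """

    __slots__ = ("data", "subject_id", "site")

    def __init__(self, data: np.ndarray, subject_id: str, site: int) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("subject data must be a 2-D voxels x timepoints matrix")
        self.data = data
        self.subject_id = subject_id
        self.site = site

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubjectMatrix({self.subject_id!r}, {self.data.shape[0]}x{self.data.shape[1]})"


@dataclass
class SiteState:
    """A site's private subjects plus its derived local statistics."""

    index: int
    subjects: List[SubjectMatrix] = field(default_factory=list)
    #: scratch space for locally derived statistics (PCA factors, windows,
    #: local centroids ...), keyed by stage name.  Never read by other sites.
    store: Dict[str, Any] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class Message:
    """A single whitelisted statistics payload in flight."""

    kind: str
    payload: np.ndarray
    src: int
    dst: int

    def __post_init__(self) -> None:
        if self.kind not in MESSAGE_WHITELIST:
            raise PrivacyViolation(
                f"message kind {self.kind!r} is not on the whitelist {sorted(MESSAGE_WHITELIST)}"
            )
        if isinstance(self.payload, SubjectMatrix):
            raise PrivacyViolation("raw subject data may never be sent between sites")
        if not isinstance(self.payload, np.ndarray):
            raise PrivacyViolation("only numeric array statistics may be sent between sites")

    @property
    def nbytes(self) -> int:
        return int(self.payload.nbytes)


@dataclass(frozen=True)
class TrafficRecord:
    step: int
    kind: str
    src: int
    dst: int
    rows: int
    cols: int
    nbytes: int
    payload: Optional[np.ndarray]


class Channel:
    """Message channel between sites: whitelist enforcement + traffic log.

    Payloads are copied on delivery, so a receiver can never mutate the
    sender's state through a shared buffer.  With ``keep_payloads`` the log
    retains payload copies for post-hoc privacy auditing.
    """

    def __init__(self, keep_payloads: bool = True) -> None:
        self.keep_payloads = keep_payloads
        self.log: List[TrafficRecord] = []

    def send(self, msg: Message) -> np.ndarray:
        """Deliver ``msg``; returns the (copied) payload for the receiver."""
        payload = np.array(msg.payload, copy=True)
        rows, cols = (payload.shape + (1, 1))[:2]
        self.log.append(
            TrafficRecord(
                step=len(self.log),
                kind=msg.kind,
                src=msg.src,
                dst=msg.dst,
                rows=int(rows),
                cols=int(cols),
                nbytes=msg.nbytes,
                payload=payload if self.keep_payloads else None,
            )
        )
        return payload

    def count(self, kind: Optional[str] = None) -> int:
        if kind is None:
            return len(self.log)
        return sum(1 for rec in self.log if rec.kind == kind)

    def total_bytes(self) -> int:
        return sum(rec.nbytes for rec in self.log)

    def to_table(self) -> str:
        """Render the traffic log as delimited text (one row per message)."""
        buf = io.StringIO()
        buf.write("step\tkind\tsrc\tdst\trows\tcols\tbytes\n")
        for rec in self.log:
            buf.write(
                f"{rec.step}\t{rec.kind}\t{rec.src}\t{rec.dst}\t{rec.rows}\t{rec.cols}\t{rec.nbytes}\n"
            )
        return buf.getvalue()


class Consortium:
    """An ordered collection of sites, a random site order and an aggregator.

    The aggregator is the terminal site of the random order, i.e. the site
    where the serial round-robin reduction ends up.
    """

    def __init__(self, sites: Sequence[SiteState], order: np.ndarray, seed: int,
                 channel: Optional[Channel] = None) -> None:
        if len(sites) == 0:
            raise ValueError("a consortium needs at least one site")
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(len(sites))):
            raise ValueError("order must be a permutation of the site indices")
        self.sites = list(sites)
        self.order = order
        self.seed = seed
        self.channel = channel if channel is not None else Channel()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def aggregator_index(self) -> int:
        """Index of the aggregator site: the last site in the order."""
        return int(self.order[-1])

    @property
    def aggregator(self) -> SiteState:
        return self.sites[self.aggregator_index]

    def ordered_sites(self) -> List[SiteState]:
        return [self.sites[i] for i in self.order]

    def subjects(self) -> List[SubjectMatrix]:
        """All subjects across sites (site order)."""
        return [sub for site in self.sites for sub in site.subjects]

    def send(self, kind: str, payload: np.ndarray, src: int, dst: int) -> np.ndarray:
        return self.channel.send(Message(kind=kind, payload=payload, src=src, dst=dst))

    def broadcast(self, kind: str, payload: np.ndarray, src: int) -> None:
        """Send ``payload`` from ``src`` to every other site."""
        for site in self.sites:
            if site.index != src:
                site.store[kind] = self.send(kind, payload, src, site.index)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Consortium(s={self.n_sites}, aggregator={self.aggregator_index})"


def build_consortium(
    site_subject_counts: Sequence[int],
    seed: int,
    subjects: Optional[Iterable[np.ndarray]] = None,
    keep_payloads: bool = True,
) -> Consortium:
    """Build a consortium with the given per-site subject counts.

    Parameters
    ----------
    site_subject_counts
        Number of subjects each site holds; all counts must be >= 1.
    seed
        Seeds the random site order (and is recorded for provenance).
    subjects
        Optional voxels x timepoints matrices, assigned to sites in
        sequence.  If omitted, sites are created empty and data is attached
        later (e.g. by the synthetic generator or a loader).
    """
    counts = [int(c) for c in site_subject_counts]
    if len(counts) == 0:
        raise ValueError("empty consortium: need at least one site")
    if any(c < 1 for c in counts):
        raise ValueError("every site must hold at least one subject")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(counts))

    sites = [SiteState(index=i) for i in range(len(counts))]
    if subjects is not None:
        pool = list(subjects)
        if len(pool) != sum(counts):
            raise ValueError(
                f"got {len(pool)} subjects for {sum(counts)} slots"
            )
        cursor = 0
        for site, c in zip(sites, counts):
            for m in range(c):
                site.subjects.append(
                    SubjectMatrix(pool[cursor], subject_id=f"s{site.index}_sub{m}", site=site.index)
                )
                cursor += 1
    else:
        # record the expected counts so loaders can validate later
        for site, c in zip(sites, counts):
            site.store["expected_subjects"] = c

    return Consortium(sites, order, seed, channel=Channel(keep_payloads=keep_payloads))


def privacy_audit(consortium: Consortium, max_cols: int, atol: float = 1e-8) -> None:
    """Audit the traffic log after a run; raises :class:`PrivacyViolation`.

    Two checks: (1) no logged payload is wider than ``max_cols`` columns
    (statistics must be low-rank summaries, never full time series); (2) no
    payload column is, up to sign and scale, equal to a raw subject data
    column (cosine similarity above ``1 - atol``).
    """
    records = [rec for rec in consortium.channel.log if rec.payload is not None]
    for rec in records:
        if rec.cols > max_cols:
            raise PrivacyViolation(
                f"payload at step {rec.step} has {rec.cols} columns > allowed {max_cols}"
            )

    # normalized raw columns, grouped by voxel dimension
    raw: Dict[int, List[np.ndarray]] = {}
    for sub in consortium.subjects():
        raw.setdefault(sub.n_voxels, []).append(sub.data)
    raw_normed = {}
    for d, blocks in raw.items():
        R = np.hstack(blocks)
        norms = np.linalg.norm(R, axis=0)
        norms[norms == 0] = 1.0
        raw_normed[d] = R / norms

    for rec in records:
        P = rec.payload
        if P.ndim != 2 or P.shape[0] not in raw_normed:
            continue
        norms = np.linalg.norm(P, axis=0)
        norms[norms == 0] = 1.0
        Pn = P / norms
        sim = np.abs(Pn.T @ raw_normed[P.shape[0]])
        if sim.size and sim.max() > 1.0 - atol:
            raise PrivacyViolation(
                f"payload at step {rec.step} contains a column proportional to a raw subject column"
            )
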