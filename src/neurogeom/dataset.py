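"""Labeled neural population datasets.

A :class:`LabeledDataset` pairs a ``T x N`` table of neural states (firing
rates or spike counts for ``N`` neurons at ``T`` time points) with a
``T x M`` table of behavioral labels (e.g. x position, y position, running
speed).  Every estimator and analysis in this package consumes this pair.

Labels may be circular (e.g. an angle on a ring); circular labels carry a
finite period used by periodic kernels and wrapped distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LabelMeta:
    """Metadata for a single label dimension."""

    name: str
    circular: bool = False
    period: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.circular:
            if self.period is None or not np.isfinite(self.period) or self.period <= 0:
                raise ValueError(
                    f"circular label {self.name!r} requires a finite positive period"
                )


@dataclass
class LabeledDataset:
    """Neural states with aligned behavioral labels.

    Parameters
    ----------
    states : (T, N) array
        Neural states; one row per time point, one column per neuron.
    labels : (T, M) array
        Label values aligned row-by-row with ``states``.
    label_meta : sequence of LabelMeta
        One entry per label column.
    provenance : dict
        Free-form metadata (seeds, generator parameters, source files).
    """

    states: np.ndarray
    labels: np.ndarray
    label_meta: tuple[LabelMeta, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if self.states.ndim != 2 or self.labels.ndim != 2:
            raise ValueError("states and labels must be 2-D tables")
        if self.states.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"row mismatch: {self.states.shape[0]} states vs "
                f"{self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite values")
        if not np.all(np.isfinite(self.labels)):
            raise ValueError("labels contain non-finite values")
        self.label_meta = tuple(self.label_meta)
        if len(self.label_meta) != self.labels.shape[1]:
            raise ValueError("label_meta length must match label columns")

    # -- basic accessors -------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.states.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.states.shape[1]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.label_meta)

    def label_index(self, name: str) -> int:
        try:
            return self.label_names.index(name)
        except ValueError:
            raise KeyError(f"no label named {name!r}; have {self.label_names}")

    def label(self, name: str) -> np.ndarray:
        return self.labels[:, self.label_index(name)]

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Row-subset view copied into a new dataset."""
        rows = np.asarray(rows)
        return LabeledDataset(
            states=self.states[rows],
            labels=self.labels[rows],
            label_meta=self.label_meta,
            provenance=dict(self.provenance),
        )

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        """Write the dataset to an NPZ archive.

        Layout: ``states``, ``labels``, per-label metadata arrays and a
        JSON-encoded provenance blob.
        """
        import json

        np.savez_compressed(
            path,
            states=self.states,
            labels=self.labels,
            label_names=np.array([m.name for m in self.label_meta]),
            label_circular=np.array([m.circular for m in self.label_meta]),
            label_period=np.array(
                [m.period if m.period is not None else np.nan for m in self.label_meta]
            ),
            label_units=np.array([m.units for m in self.label_meta]),
            provenance=np.array(json.dumps(self.provenance, default=str)),
        )

    @classmethod
    def load(cls, path) -> "LabeledDataset":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = tuple(
                LabelMeta(
                    name=str(n),
                    circular=bool(c),
                    period=None if np.isnan(p) else float(p),
                    units=str(u),
                )
                for n, c, p, u in zip(
                    z["label_names"],
                    z["label_circular"],
                    z["label_period"],
                    z["label_units"],
                )
            )
            return cls(
                states=z["states"],
                labels=z["labels"],
                label_meta=meta,
                provenance=json.loads(str(z["provenance"])),
            )


def spatial_meta(units: str = "cm") -> tuple[LabelMeta, LabelMeta, LabelMeta]:
    """Standard (x, y, speed) label metadata for open-field data."""
    return (
        LabelMeta("x", units=units),
        LabelMeta("y", units=units),
        LabelMeta("speed", units=f"{units}/s"),
    )
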