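"""Model/Results facade over the topology pipeline.

:class:`TopologyModel` is built from a network (or records, or a table on
disk); its :meth:`~TopologyModel.fit` computes every topological parameter
and the topology classification and returns a :class:`TopologyResults`
carrying the estimates, their fit diagnostics and a printable summary
table using the field's conventional parameter names ("N°nodes",
"Clustering coefficient", "Char. path length", ...), so the output can sit
side by side with published topology tables.  Simulation (node-deletion
experiments) and plotting hang off the results object.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .attacks import AttackComparison, AttackResult, compare_attacks, random_attack, targeted_attack
from .classify import ClassificationThresholds, NetworkClass, classify_topology
from .network import SignalingNetwork, build_network
from .records import InteractionRecord, read_interaction_table
from .sifio import read_sif
from .topology import TopologySummary, summarize_topology

__all__ = ["TopologyModel", "TopologyResults", "summary_rows"]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.3f}"
    return str(x)


def summary_rows(s: TopologySummary) -> list[tuple[str, str]]:
    """(parameter, value) rows in the conventional table layout."""
    rows = [
        ("N°nodes", _fmt(s.n_nodes)),
        ("N°edges", _fmt(s.n_edges)),
        ("Clustering coefficient", _fmt(s.mean_clustering)),
        ("Diameter", _fmt(s.diameter)),
        ("Averaged n°neighbours", _fmt(s.avg_neighbors)),
        ("Char. path length", _fmt(s.char_path_length)),
    ]
    for label, fit in (("IN", s.in_fit), ("OUT", s.out_fit)):
        if fit is not None:
            rows += [
                (f"{label} degree b", _fmt(fit.b)),
                (f"{label} degree r", _fmt(fit.r)),
                (f"{label} degree R^2", _fmt(fit.r2)),
            ]
        else:
            rows.append((f"{label} degree fit", "unfittable"))
    if s.ck_fit is not None:
        rows += [
            ("C(k) b", _fmt(s.ck_fit.b)),
            ("C(k) r", _fmt(s.ck_fit.r)),
            ("C(k) R^2", _fmt(s.ck_fit.r2)),
        ]
    else:
        rows.append(("C(k) fit", "unfittable"))
    rows += [
        ("% one-link nodes", _fmt(100 * s.frac_k1)),
        ("% two-link nodes", _fmt(100 * s.frac_k2)),
        ("% activation edges", _fmt(100 * s.frac_activation)),
        ("% inhibition edges", _fmt(100 * s.frac_inhibition)),
    ]
    if s.hub_list:
        hubs = "; ".join(f"{label} ({k})" for label, k in s.hub_list[:5])
        rows.append(("Hubs (n°links)", hubs))
    return rows


class TopologyModel:
    """Topological model of one directed signed signaling network."""

    def __init__(
        self,
        network: SignalingNetwork,
        *,
        path_mode: Literal["directed", "undirected"] = "directed",
        thresholds: ClassificationThresholds | None = None,
    ):
        self.network = network
        self.path_mode = path_mode
        self.thresholds = thresholds or ClassificationThresholds()

    @classmethod
    def from_records(
        cls,
        records: Sequence[InteractionRecord],
        *,
        exclusion: Iterable[str] = (),
        name: str = "",
        **kwargs,
    ) -> "TopologyModel":
        return cls(build_network(records, exclusion=exclusion, name=name), **kwargs)

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        *,
        delimiter: str = ",",
        header: bool = True,
        exclusion: Iterable[str] = (),
        **kwargs,
    ) -> "TopologyModel":
        records = read_interaction_table(path, delimiter=delimiter, header=header)
        return cls.from_records(
            records, exclusion=exclusion, name=Path(path).stem, **kwargs
        )

    @classmethod
    def from_sif(cls, path: str | Path, **kwargs) -> "TopologyModel":
        return cls(read_sif(path, name=Path(path).stem), **kwargs)

    def fit(self) -> "TopologyResults":
        summary = summarize_topology(self.network, path_mode=self.path_mode)
        classification = classify_topology(summary, self.thresholds)
        return TopologyResults(self, summary, classification)


@dataclass
class TopologyResults:
    """Fitted topology: parameter block, fits, classification, experiments."""

    model: TopologyModel
    topology: TopologySummary
    classification: NetworkClass

    @property
    def network(self) -> SignalingNetwork:
        return self.model.network

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        s = self.topology
        rows = summary_rows(s) + [("Topology class", self.classification.label)]
        width = max(len(name) for name, _ in rows)
        head = f"Topology summary: {s.name or '<unnamed>'} ({s.path_mode} paths)"
        bar = "=" * max(len(head), width + 12)
        lines = [head, bar]
        lines += [f"{name:<{width}}  {value}" for name, value in rows]
        return "\n".join(lines)

    def to_rows(self) -> list[tuple[str, str]]:
        return summary_rows(self.topology) + [("Topology class", self.classification.label)]

    def to_tsv(self) -> str:
        return "\n".join(f"{name}\t{value}" for name, value in self.to_rows()) + "\n"

    def to_dict(self) -> dict:
        s = self.topology

        def fit_block(fit):
            if fit is None:
                return None
            return {"a": fit.a, "b": fit.b, "r": fit.r, "r2": fit.r2, "n_points": fit.n_points}

        ev = {
            k: v
            for k, v in self.classification.evidence.items()
            if k != "thresholds"
        }
        return {
            "name": s.name,
            "n_nodes": s.n_nodes,
            "n_edges": s.n_edges,
            "clustering_coefficient": s.mean_clustering,
            "diameter": s.diameter,
            "avg_neighbors": s.avg_neighbors,
            "char_path_length": s.char_path_length,
            "in_fit": fit_block(s.in_fit),
            "out_fit": fit_block(s.out_fit),
            "ck_fit": fit_block(s.ck_fit),
            "hubs": [list(h) for h in s.hub_list],
            "frac_k1": s.frac_k1,
            "frac_k2": s.frac_k2,
            "frac_activation": s.frac_activation,
            "frac_inhibition": s.frac_inhibition,
            "frac_other": s.frac_other,
            "path_mode": s.path_mode,
            "topology_class": self.classification.label,
            "classification_evidence": ev,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    # -- simulation --------------------------------------------------------
    def attack(
        self,
        *,
        n_remove: int | None = None,
        labels: Iterable[str] | None = None,
        summarize: bool = True,
    ) -> AttackResult:
        return targeted_attack(self.network, n_remove=n_remove, labels=labels, summarize=summarize)

    def random_attack(
        self, n_remove: int, seed: int, n_reps: int = 1, *, summarize: bool = True
    ) -> list[AttackResult]:
        return random_attack(self.network, n_remove, seed, n_reps, summarize=summarize)

    def compare_attacks(
        self, n_remove: int, n_reps: int, seed: int, *, summarize: bool = False
    ) -> AttackComparison:
        return compare_attacks(self.network, n_remove, n_reps, seed, summarize=summarize)

    # -- plotting ----------------------------------------------------------
    def plot_degree_distribution(self, mode: str = "in", ax=None):
        """Log-log degree histogram with the fitted power law overlaid."""
        import matplotlib.pyplot as plt
        import numpy as np

        dist = {
            "in": self.topology.in_dist,
            "out": self.topology.out_dist,
            "total": self.topology.total_dist,
        }[mode]
        fit = {"in": self.topology.in_fit, "out": self.topology.out_fit, "total": None}.get(mode)
        if ax is None:
            _, ax = plt.subplots()
        if dist is not None and dist.points:
            ks = [k for k, _ in dist.points]
            cs = [c for _, c in dist.points]
            ax.loglog(ks, cs, "o", label=f"{mode}-degree counts")
            if fit is not None:
                kk = np.linspace(min(ks), max(ks), 50)
                ax.loglog(kk, fit.expected(kk), "-", label=f"a·k^b, b={fit.b:.2f}")
        ax.set_xlabel("degree k")
        ax.set_ylabel("node count")
        ax.legend()
        return ax
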