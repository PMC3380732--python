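"""Regulator catalogs: predicted TF→target and microRNA-family→target pairs.

These catalogs are produced upstream (promoter scanning for TFs, seed-match
prediction for microRNA families) and consumed here as plain tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _dedup(items):
    return list(dict.fromkeys(items))


@dataclass
class RegulatorCatalog:
    """Candidate regulators per target gene.

    ``tf_targets``
        target gene id → ordered, de-duplicated list of TF ids.
    ``tf_encoding``
        TF id → id of the gene encoding the TF (its mRNA proxy).
    ``mirna_targets``
        target gene id → ordered, de-duplicated list of microRNA family ids.
    """

    tf_targets: dict[str, list[str]] = field(default_factory=dict)
    tf_encoding: dict[str, str] = field(default_factory=dict)
    mirna_targets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tf_targets = {g: _dedup(v) for g, v in self.tf_targets.items()}
        self.mirna_targets = {g: _dedup(v) for g, v in self.mirna_targets.items()}

    def candidates(self, gene: str, kind: str) -> list[str]:
        table = self.tf_targets if kind == "tf" else self.mirna_targets
        return table.get(gene, [])

    def feature_of(self, regulator: str, kind: str) -> str:
        """Expression feature measuring a regulator: the encoding gene for a
        TF, the family id itself for a microRNA."""
        if kind == "tf":
            return self.tf_encoding.get(regulator, regulator)
        return regulator
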