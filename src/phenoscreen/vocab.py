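"""Endpoint vocabulary for the 12-system primary-cell screening panel.

Each endpoint is one biomarker measured in one stimulated co-culture system
and is keyed ``"SYSTEM:Biomarker"`` (e.g. ``"3C:SRB"``, ``"BT:sIgG"``).  The
default vocabulary reproduces the shape of the 148-endpoint Diversity panel:
every adherent system carries an SRB total-protein readout, the suspension-cell
systems (SAg, BT) carry PBMC viability readouts, and five systems carry
proliferation readouts.  Loss-of-signal endpoints (``is_down_readout``) are the
ones whose canonical response direction is a decrease; they are sign-inverted
before hit calling so that all responses point in the positive direction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

SYSTEMS: tuple[str, ...] = (
    "3C", "4H", "LPS", "SAg", "BT", "BE3C",
    "BF4T", "HDF3CGF", "KF3CT", "CASM3C", "MyoF", "Mphg",
)

#: Systems containing endothelial cells (HUVEC); used by the acute-toxicity rule.
ENDOTHELIAL_SYSTEMS: frozenset[str] = frozenset({"3C", "4H", "LPS", "Mphg"})

ROLES: frozenset[str] = frozenset({
    "srb_total_protein", "pbmc_cytotoxicity", "proliferation",
    "igg_secretion", "biomarker",
})

#: Roles whose endpoints count as cytotoxicity readouts.
CYTOTOX_ROLES: frozenset[str] = frozenset({"srb_total_protein", "pbmc_cytotoxicity"})


@dataclass(frozen=True)
class EndpointDef:
    """Definition of one assay endpoint."""

    endpoint_id: str
    system: str
    biomarker: str
    is_down_readout: bool = False
    roles: frozenset = field(default_factory=lambda: frozenset({"biomarker"}))

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r} for {self.endpoint_id!r}")
        if self.endpoint_id != f"{self.system}:{self.biomarker}":
            raise ValueError(
                f"endpoint_id {self.endpoint_id!r} must be 'SYSTEM:Biomarker'"
            )
        bad = set(self.roles) - ROLES
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)} for {self.endpoint_id!r}")

    @property
    def is_endothelial_system(self) -> bool:
        return self.system in ENDOTHELIAL_SYSTEMS

    @property
    def is_cytotox_role(self) -> bool:
        return bool(set(self.roles) & CYTOTOX_ROLES)


class Vocabulary:
    """Ordered, keyed collection of :class:`EndpointDef`."""

    def __init__(self, endpoints: Iterable[EndpointDef]):
        self._by_id: dict[str, EndpointDef] = {}
        for ep in endpoints:
            if ep.endpoint_id in self._by_id:
                raise ValueError(f"duplicate endpoint_id {ep.endpoint_id!r}")
            self._by_id[ep.endpoint_id] = ep

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[EndpointDef]:
        return iter(self._by_id.values())

    def __contains__(self, endpoint_id: str) -> bool:
        return endpoint_id in self._by_id

    def __getitem__(self, endpoint_id: str) -> EndpointDef:
        try:
            return self._by_id[endpoint_id]
        except KeyError:
            raise KeyError(f"endpoint {endpoint_id!r} not in vocabulary") from None

    @property
    def endpoint_ids(self) -> list[str]:
        return list(self._by_id)

    def with_role(self, role: str) -> list[str]:
        return [e.endpoint_id for e in self if role in e.roles]

    @property
    def cytotox_endpoints(self) -> list[str]:
        """Endpoints with a cytotoxicity role (SRB total protein or PBMC viability)."""
        return [e.endpoint_id for e in self if e.is_cytotox_role]

    @property
    def srb_endpoints(self) -> list[str]:
        return self.with_role("srb_total_protein")

    @property
    def down_endpoints(self) -> list[str]:
        return [e.endpoint_id for e in self if e.is_down_readout]

    # -- CSV interchange ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["endpoint_id", "system", "biomarker", "is_down", "roles"])
            for ep in self:
                w.writerow([
                    ep.endpoint_id, ep.system, ep.biomarker,
                    int(ep.is_down_readout), ";".join(sorted(ep.roles)),
                ])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Vocabulary":
        eps = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"endpoint_id", "system", "biomarker", "is_down", "roles"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"vocabulary CSV missing columns: {sorted(missing)}")
            for row in reader:
                eps.append(EndpointDef(
                    endpoint_id=row["endpoint_id"],
                    system=row["system"],
                    biomarker=row["biomarker"],
                    is_down_readout=bool(int(row["is_down"])),
                    roles=frozenset(row["roles"].split(";")),
                ))
        return cls(eps)


# --------------------------------------------------------------------------
# Default 148-endpoint panel.
#
# Biomarker lists follow the published panel composition: SRB total protein in
# every adherent system (all but BT), PBMC viability in SAg and BT,
# proliferation in 3C, SAg, BT, HDF3CGF and CASM3C, and system-typical
# inflammatory / tissue-remodeling biomarkers elsewhere.

_PANEL: dict[str, list[str]] = {
    "3C": ["SRB", "Proliferation", "TF", "MCP-1", "VCAM-1", "ICAM-1",
           "E-selectin", "IL-8", "MIG", "HLA-DR", "uPAR", "Eotaxin-3",
           "Thrombomodulin"],
    "4H": ["SRB", "MCP-1", "Eotaxin-3", "VCAM-1", "P-selectin", "uPAR",
           "VEGFR2", "IL-8"],
    "LPS": ["SRB", "PGE2", "sTNFα", "sIL-10", "sIL-1α", "IL-8", "MCP-1",
            "E-selectin", "CD40", "CD69", "M-CSF", "TF"],
    "SAg": ["SRB", "Proliferation", "PBMC Cytotoxicity", "MCP-1", "CD38",
            "CD40", "CD69", "E-selectin", "IL-8", "MIG", "sIL-17A", "sTNFα"],
    "BT": ["sIgG", "Proliferation", "PBMC Cytotoxicity", "sIL-17A", "sIL-17F",
           "sIL-2", "sIL-6", "sTNFα", "sIgM", "CD40", "CD69", "B cell Viability"],
    "BE3C": ["SRB", "HLA-DR", "sIL-1α", "IP-10", "I-TAC", "IL-8", "MIG",
             "MMP-1", "MMP-9", "PAI-1", "tPA", "uPA", "uPAR"],
    "BF4T": ["SRB", "MCP-1", "Eotaxin-3", "VCAM-1", "ICAM-1", "IL-8",
             "sIL-1α", "Keratin 8/18", "MMP-1", "MMP-3", "MMP-9", "PAI-1",
             "tPA", "uPA"],
    "HDF3CGF": ["SRB", "Proliferation", "Collagen I", "Collagen III",
                "Collagen IV", "VCAM-1", "ICAM-1", "IP-10", "I-TAC", "IL-8",
                "MIG", "MCP-1", "MMP-1", "PAI-1", "TIMP-1", "TIMP-2"],
    "KF3CT": ["SRB", "MCP-1", "ICAM-1", "IP-10", "sIL-1α", "MIG", "MMP-9",
              "PAI-1", "TIMP-2", "uPA", "TGF-β1"],
    "CASM3C": ["SRB", "Proliferation", "SAA", "MCP-1", "VCAM-1",
               "Thrombomodulin", "TF", "uPAR", "sIL-6", "IL-8", "MIG",
               "HLA-DR", "M-CSF", "LDLR"],
    "MyoF": ["SRB", "α-SM Actin", "Collagen I", "Collagen III", "Collagen IV",
             "IL-8", "MCP-1", "MMP-1", "PAI-1", "TIMP-1", "Decorin"],
    "Mphg": ["SRB", "sIL-10", "MCP-1", "MIP-1α", "IL-8", "sIL-1α",
             "E-selectin", "CD40", "CD69", "VCAM-1", "sTNFα", "M-CSF"],
}

#: Loss-of-signal biomarkers beyond the role-implied ones: canonical responses
#: at these endpoints are decreases (e.g. immunosuppressive cytokine loss in
#: the T/B-cell co-culture, collagen loss in the fibroblast system).
_EXTRA_DOWN: frozenset[str] = frozenset({
    "BT:sIL-17A", "BT:sIL-17F", "BT:sIL-2", "BT:sIL-6", "BT:sTNFα",
    "BT:sIgM", "BT:B cell Viability",
    "Mphg:sIL-10",
    "HDF3CGF:Collagen III",
})


def _roles_for(system: str, biomarker: str) -> frozenset[str]:
    if biomarker == "SRB":
        return frozenset({"srb_total_protein"})
    if biomarker == "PBMC Cytotoxicity":
        return frozenset({"pbmc_cytotoxicity"})
    if biomarker == "Proliferation":
        return frozenset({"proliferation"})
    if biomarker == "sIgG":
        return frozenset({"igg_secretion"})
    return frozenset({"biomarker"})


def default_vocabulary() -> Vocabulary:
    """The default 148-endpoint panel across the 12 systems."""
    eps: list[EndpointDef] = []
    for system, biomarkers in _PANEL.items():
        for biomarker in biomarkers:
            eid = f"{system}:{biomarker}"
            roles = _roles_for(system, biomarker)
            down = (
                eid in _EXTRA_DOWN
                or bool(roles & {"srb_total_protein", "pbmc_cytotoxicity",
                                 "proliferation", "igg_secretion"})
            )
            eps.append(EndpointDef(eid, system, biomarker, down, roles))
    return Vocabulary(eps)
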