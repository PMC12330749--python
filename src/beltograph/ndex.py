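"""NDEx upload contract.

NDEx is an online exchange for sharing networks.  Only the save-network
surface is modeled: a client with ``save_network(cx2_document) -> id``.
Upload is a pure pass-through of :func:`beltograph.cx2.graph_to_cx2`
output, so any client implementing the protocol (the official ndex2
client wrapped in an adapter, or a mock in tests) behaves identically.
"""

from __future__ import annotations

from typing import Protocol

from .cx2 import graph_to_cx2
from .graph import KnowledgeGraph


class NDExAuthError(RuntimeError):
    """Missing or rejected NDEx credentials."""


class NDExServiceError(RuntimeError):
    """The NDEx service rejected the upload."""


class NDExClient(Protocol):
    def save_network(self, cx2_document: list[dict]) -> str:
        """Upload a CX2 document; return the service-assigned network id."""
        ...


def upload_network(graph: KnowledgeGraph, client: NDExClient) -> str:
    """Serialize ``graph`` to CX2 and upload it through ``client``."""
    return client.save_network(graph_to_cx2(graph))
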