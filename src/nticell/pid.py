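"""Minimal-mutual-information partial information decomposition fingerprint.

Under the min-MI redundancy measure, Rdn = min(I(X;X'), I(C;X')) and, since
NTIC = Rdn - Syn, synergy follows as Syn = Rdn - NTIC.  When self-prediction
dominates sibling-to-future coupling (I(X;X') > I(C;X'), the *dominance*
condition), Rdn = I(C;X') and information closure (NTIC ~ 0) forces
Syn ~ Rdn > 0: the collective genuinely co-constructs the cell's future.
The three regimes map onto qualitative fingerprints:

* coupled:               Rdn > Syn
* information closure:   Rdn ~ Syn > 0
* independent:           Rdn ~ Syn ~ 0
"""

from __future__ import annotations

from dataclasses import dataclass

from .estimators import InfoTriple

__all__ = ["PIDFingerprint", "pid_fingerprint"]

FINGERPRINTS = ("Rdn>Syn", "Rdn~Syn>0", "Rdn~Syn~0")


@dataclass(frozen=True)
class PIDFingerprint:
    """Redundancy/synergy reading of one cell's information triple (bits)."""

    redundancy: float
    synergy: float
    dominance_holds: bool
    regime_fingerprint: str


def pid_fingerprint(triple: InfoTriple, tolerance: float = 0.01) -> PIDFingerprint:
    """Map an information triple onto its PID fingerprint.

    ``tolerance`` (bits) decides when two quantities count as equal; a
    natural choice is half the width of the cell's surrogate NTIC interval,
    tying resolution to that cell's estimated noise.
    """
    rdn = min(triple.mi_self, triple.mi_ctx)
    syn = rdn - triple.ntic
    if abs(rdn - syn) <= tolerance:
        fp = "Rdn~Syn>0" if max(rdn, syn) > tolerance else "Rdn~Syn~0"
    elif rdn > syn:
        fp = "Rdn>Syn"
    else:
        fp = "Rdn~Syn>0" if min(rdn, syn) > tolerance else "Rdn~Syn~0"
    return PIDFingerprint(
        redundancy=rdn,
        synergy=syn,
        dominance_holds=triple.mi_self > triple.mi_ctx,
        regime_fingerprint=fp,
    )
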