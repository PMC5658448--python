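"""Canonical ligand parameter sets for the NK1 receptor system.

SP (substance P) and NKA (neurokinin A) carry published kon/koff values; the
radioligand is an SP analogue whose own rate constants are not separately
published, so it defaults to SP's (a documented assumption).  The two
antagonist stand-ins are synthetic: their koff values follow the reported
kinetic behaviour (aprepitant dissociates at ~0.0054 min^-1; desfluoro
aprepitant's KRI of ~1 puts its koff near the radioligand's) and their kon
values are back-calculated from the published affinities (pKi 9.5 and 9.3).
They are fixtures for simulation studies, not measured rate constants.
"""

from .kinetics import LigandKinetics

__all__ = ["SP", "NKA", "RADIOLIGAND", "APREPITANT_LIKE", "DFA_LIKE"]

#: Substance P: fast-associating, slowly dissociating endogenous agonist.
SP = LigandKinetics("SP", kon=0.24, koff=0.027, role="agonist")

#: Neurokinin A: associates ~240-fold slower than SP and dissociates faster.
NKA = LigandKinetics("NKA", kon=0.0010, koff=0.19, role="agonist")

#: SP-analogue radioligand (~2.5 nM in the dual-point assay); SP kinetics assumed.
RADIOLIGAND = LigandKinetics("radioligand", kon=0.24, koff=0.027, role="radioligand")

#: Slowly dissociating antagonist stand-in (synthetic): koff 0.0054 min^-1,
#: KD 10^-9.5 M = 0.316 nM -> kon = koff/KD.
APREPITANT_LIKE = LigandKinetics(
    "aprepitant_like", kon=0.0054 / 10 ** (9 - 9.5), koff=0.0054, role="antagonist"
)

#: Fast-dissociating antagonist stand-in (synthetic): koff matched to the
#: radioligand's (KRI ~ 1), KD 10^-9.3 M = 0.501 nM -> kon = koff/KD.
DFA_LIKE = LigandKinetics(
    "dfa_like", kon=0.027 / 10 ** (9 - 9.3), koff=0.027, role="antagonist"
)
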