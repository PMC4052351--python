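"""Published extracellular-loop definitions for 13 GPCR crystal structures.

Registry of ECL2 residue ranges and sequences (author numbering of the
crystal structure named per receptor) used as inputs to loop restoration,
together with a small set of ECL1/ECL3 entries.  Keys are receptor short
names; values are :class:`~ecloop.structure_io.LoopDefinition`.
"""

from __future__ import annotations

from .structure_io import LoopDefinition

#: PDB entry each loop numbering refers to.
CRYSTAL_STRUCTURES = {
    "A2AR": "4EIY", "B1AR": "2Y00", "B2AR": "2RH1", "M2R": "3UON",
    "M3R": "4DAJ", "CXCR4": "3ODU", "D3R": "3PBL", "NTR1": "4GRV",
    "DOR": "4EJ4", "NOP": "4EA3", "MOR": "4DKL", "RHO": "1U19",
    "S1PR": "3V2W",
}

#: Second extracellular loop (TMH4-TMH5) for each receptor.
ECL2 = {
    "A2AR": LoopDefinition("ECL2", 139, 172, "PMLGWNNCGQPKEGKNHSQGCGEGQVACLFEDVV"),
    "B1AR": LoopDefinition("ECL2", 181, 203, "WWRDEDPQALKCYQDPGCCDFVT"),
    "B2AR": LoopDefinition("ECL2", 173, 195, "WYRATHQEAINCYANETCCDFFT"),
    "M2R": LoopDefinition("ECL2", 168, 182, "VRTVEDGECYIQFFS"),
    "M3R": LoopDefinition("ECL2", 212, 226, "KRTVPPGECFIQFLS"),
    "CXCR4": LoopDefinition("ECL2", 176, 191, "NVSEADDRYICDRFYP"),
    "D3R": LoopDefinition("ECL2", 172, 184, "FNTTGDPTVCSIS"),
    "NTR1": LoopDefinition("ECL2", 209, 229, "GLQNRSGDGTHPGGLVCTPIV"),
    "DOR": LoopDefinition("ECL2", 188, 204, "VTQPRDGAVVCMLQFPS"),
    "MOR": LoopDefinition("ECL2", 207, 223, "TTKYRQGSIDCTLTFSH"),
    "NOP": LoopDefinition("ECL2", 190, 206, "SAQVEDEEIECLVEIPT"),
    "RHO": LoopDefinition("ECL2", 175, 198, "WSRYIPEGMQCSCGIDYYTPHEET"),
    "S1PR": LoopDefinition("ECL2", 182, 198, "WNCISALSSCSTVLPLY"),
}

#: First and third extracellular loops (subset with self-consistent numbering).
OTHER_LOOPS = {
    ("A2AR", "ECL1"): LoopDefinition("ECL1", 70, 72, "FCA"),
    ("A2AR", "ECL3"): LoopDefinition("ECL3", 260, 265, "PDCSHA"),
    ("D3R", "ECL1"): LoopDefinition("ECL1", 93, 98, "GGVWNF"),
    ("RHO", "ECL1"): LoopDefinition("ECL1", 102, 105, "YFVF"),
}
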