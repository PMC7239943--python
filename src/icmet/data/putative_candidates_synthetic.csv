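name,formula,adduct,rt_min,hmdb_id
glutamate (candidate),C5H9NO4,[M-H]-,,HMDB0000148
O-acetylserine (candidate),C5H9NO4,[M-H]-,,HMDB0003011
N-methyl-aspartate (candidate),C5H9NO4,[M-H]-,,HMDB0002393
2-hydroxyglutarate (candidate),C5H8O5,[M-H]-,,HMDB0000694
2-oxoglutarate (candidate),C5H6O5,[M-H]-,,HMDB0000208
2-oxoadipate (candidate),C6H8O5,[M-H]-,,HMDB0000225
citrate (candidate),C6H8O7,[M-H]-,,HMDB0000094
lactate (candidate),C3H6O3,[M-H]-,,HMDB0000190
pyruvate (candidate),C3H4O3,[M-H]-,,HMDB0000243
succinate (candidate),C4H6O4,[M-H]-,,HMDB0000254
fumarate (candidate),C4H4O4,[M-H]-,,HMDB0000134
malate (candidate),C4H6O5,[M-H]-,,HMDB0000156
hexose monophosphate (candidate),C6H13O9P,[M-H]-,,HMDB0001401
ribose 5-phosphate (candidate),C5H11O8P,[M-H]-,,HMDB0001548
glutathione (candidate),C10H17N3O6S,[M-H]-,,HMDB0000125
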