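(-15,-15): inferior_nasal
(-15,-3): inferior_nasal
(-15,-9): inferior_nasal
(-15,15): superior_nasal
(-15,3): superior_nasal
(-15,9): superior_nasal
(-21,-3): inferior_nasal
(-21,-9): inferior_nasal
(-21,3): superior_nasal
(-21,9): superior_nasal
(-27,-3): inferior_nasal
(-27,3): superior_nasal
(-3,-15): inferior
(-3,-21): inferior
(-3,-3): central
(-3,-9): inferior
(-3,15): superior
(-3,21): superior
(-3,3): central
(-3,9): superior
(-9,-15): inferior_nasal
(-9,-21): inferior_nasal
(-9,-3): inferior_nasal
(-9,-9): inferior_nasal
(-9,15): superior_nasal
(-9,21): superior_nasal
(-9,3): superior_nasal
(-9,9): superior_nasal
(15,-15): temporal
(15,-9): temporal
(15,15): temporal
(15,9): temporal
(21,-3): temporal
(21,-9): temporal
(21,3): temporal
(21,9): temporal
(3,-15): inferior
(3,-21): inferior
(3,-3): central
(3,-9): inferior
(3,15): superior
(3,21): superior
(3,3): central
(3,9): superior
(9,-15): inferior
(9,-21): inferior
(9,-3): central
(9,-9): inferior
(9,15): superior
(9,21): superior
(9,3): central
(9,9): superior
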