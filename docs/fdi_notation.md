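# FDI (ISO 3950) tooth notation

Two digits: quadrant then position from the midline.

Quadrants: 1 = maxillary right, 2 = maxillary left, 3 = mandibular left,
4 = mandibular right.

| position | anatomical name | FDI codes (quadrants 1/2/3/4) |
|---|---|---|
| 1 | central incisor | 11, 21, 31, 41 |
| 2 | lateral incisor | 12, 22, 32, 42 |
| 3 | canine | 13, 23, 33, 43 |
| 4 | first premolar | 14, 24, 34, 44 |
| 5 | second premolar | 15, 25, 35, 45 |
| 6 | first permanent molar | 16, 26, 36, 46 |
| 7 | second permanent molar | 17, 27, 37, 47 |
| 8 | third molar | 18, 28, 38, 48 |

Examples: 31 = mandibular left central incisor; 16 = maxillary right first
molar. Third molars (position 8) are accepted by the data model but never
consumed by either estimator. FDI is used because it identifies bilateral
pairs unambiguously: the contralateral partner of a tooth keeps its
position digit and mirrors the quadrant (1↔2, 3↔4).
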