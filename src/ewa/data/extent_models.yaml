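# Default maximal-extent perfusion territories (9 rings x 24 sectors,
# 1-based [ring, sector] cells). Sector 1 starts at the anterior RV
# insertion; indices increase through the septum (1-12), then the
# inferior (13-16), lateral (17-20) and anterior (21-24) walls.
# Qualitative defaults; replace with site-specific models as needed.
# LM is derived as the union of LAD, LCx and RCA; the union leaves a
# narrow lateral strip uncovered so an LM culprit still has a remote
# reference.
{LAD: [[1, 1], [1, 2], [1, 3], [1, 4], [1, 5], [1, 6], [1, 21], [1, 22], [1, 23],
    [1, 24], [2, 1], [2, 2], [2, 3], [2, 4], [2, 5], [2, 6], [2, 21], [2, 22], [2,
      23], [2, 24], [3, 1], [3, 2], [3, 3], [3, 4], [3, 5], [3, 6], [3, 21], [3, 22],
    [3, 23], [3, 24], [4, 1], [4, 2], [4, 3], [4, 4], [4, 5], [4, 6], [4, 21], [4,
      22], [4, 23], [4, 24], [5, 1], [5, 2], [5, 3], [5, 4], [5, 5], [5, 6], [5, 21],
    [5, 22], [5, 23], [5, 24], [6, 1], [6, 2], [6, 3], [6, 4], [6, 5], [6, 6], [6,
      21], [6, 22], [6, 23], [6, 24], [7, 1], [7, 2], [7, 3], [7, 4], [7, 5], [7,
      6], [7, 7], [7, 8], [7, 18], [7, 19], [7, 20], [7, 21], [7, 22], [7, 23], [
      7, 24], [8, 1], [8, 2], [8, 3], [8, 4], [8, 5], [8, 6], [8, 7], [8, 8], [8,
      18], [8, 19], [8, 20], [8, 21], [8, 22], [8, 23], [8, 24], [9, 1], [9, 2], [
      9, 3], [9, 4], [9, 5], [9, 6], [9, 7], [9, 8], [9, 9], [9, 10], [9, 11], [9,
      12], [9, 13], [9, 14], [9, 15], [9, 16], [9, 17], [9, 18], [9, 19], [9, 20],
    [9, 21], [9, 22], [9, 23], [9, 24]], LCx: [[1, 14], [1, 15], [1, 16], [1, 17],
    [1, 18], [1, 19], [2, 14], [2, 15], [2, 16], [2, 17], [2, 18], [2, 19], [3, 14],
    [3, 15], [3, 16], [3, 17], [3, 18], [3, 19], [4, 14], [4, 15], [4, 16], [4, 17],
    [4, 18], [4, 19], [5, 14], [5, 15], [5, 16], [5, 17], [5, 18], [5, 19], [6, 14],
    [6, 15], [6, 16], [6, 17], [6, 18], [6, 19], [7, 13], [7, 14], [7, 15], [7, 16],
    [8, 13], [8, 14], [8, 15], [8, 16]], RCA: [[1, 7], [1, 8], [1, 9], [1, 10], [
      1, 11], [1, 12], [1, 13], [1, 14], [1, 15], [1, 16], [2, 7], [2, 8], [2, 9],
    [2, 10], [2, 11], [2, 12], [2, 13], [2, 14], [2, 15], [2, 16], [3, 7], [3, 8],
    [3, 9], [3, 10], [3, 11], [3, 12], [3, 13], [3, 14], [3, 15], [3, 16], [4, 7],
    [4, 8], [4, 9], [4, 10], [4, 11], [4, 12], [4, 13], [4, 14], [4, 15], [4, 16],
    [5, 7], [5, 8], [5, 9], [5, 10], [5, 11], [5, 12], [5, 13], [5, 14], [5, 15],
    [5, 16], [6, 7], [6, 8], [6, 9], [6, 10], [6, 11], [6, 12], [6, 13], [6, 14],
    [6, 15], [6, 16], [7, 9], [7, 10], [7, 11], [7, 12], [7, 13], [7, 14], [7, 15],
    [7, 16], [8, 9], [8, 10], [8, 11], [8, 12], [8, 13], [8, 14], [8, 15], [8, 16]]}
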