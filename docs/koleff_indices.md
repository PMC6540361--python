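# Incidence-based β-diversity measures

`koleff_index(x, y, id)` reduces two abundance vectors to presences
(x > 0) and computes the matching components

* `a` — bins present in both samples,
* `b` — bins present only in the first,
* `c` — bins present only in the second,

then applies one of the 24 classical pairwise measures reviewed by
Koleff and co-workers (ids follow the convention of vegan's
`betadiver`). Several ids share a pairwise formula; their multi-site
generalizations differ, which is why the ids are kept distinct.
Undefined combinations (zero denominators, logs of zero) return NaN.

| id   | formula (pairwise)                                             |
|------|----------------------------------------------------------------|
| w    | (b+c)/(2a+b+c)                                                 |
| -1   | (b+c)/(2a+b+c)                                                 |
| c    | (b+c)/2                                                        |
| wb   | b+c                                                            |
| r    | 2bc/((a+b+c)² − 2bc)                                           |
| I    | log(2a+b+c) − 2a·log2/(2a+b+c) − ((a+b)log(a+b)+(a+c)log(a+c))/(2a+b+c) |
| e    | exp(I) − 1                                                     |
| t    | (b+c)/(2a+b+c)                                                 |
| me   | (b+c)/(2a+b+c)                                                 |
| j    | a/(a+b+c)                                                      |
| sor  | 2a/(2a+b+c)                                                    |
| m    | (2a+b+c)(b+c)/(a+b+c)                                          |
| -2   | min(b,c)/(max(b,c)+a)                                          |
| co   | (ac+ab+2bc)/(2(a+b)(a+c))                                      |
| cc   | (b+c)/(a+b+c)                                                  |
| g    | (b+c)/(a+b+c)                                                  |
| -3   | min(b,c)/(a+b+c)                                               |
| l    | (b+c)/2                                                        |
| 19   | 2(bc+1)/((a+b+c)(a+b+c−1))                                     |
| hk   | (b+c)/(2a+b+c)                                                 |
| rlb  | a/(a+c)                                                        |
| sim  | min(b,c)/(min(b,c)+a)                                          |
| gl   | 2|b−c|/(2a+b+c)                                                |
| z    | (log2 − log(2a+b+c) + log(a+b+c))/log2                         |

Note that `j`, `sor` and `rlb` are similarity-shaped (1 at identity),
while most others are dissimilarity-shaped; `cytodiv` reports the
published forms verbatim and leaves complementation to the analyst.
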