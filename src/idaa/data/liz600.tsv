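size_bp
20
40
60
80
100
114
120
140
160
180
200
214
220
240
250
260
280
300
314
320
340
360
380
400
414
420
440
460
480
500
514
520
540
560
580
600
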