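subject,ocsvm,parzen,kmeans1,kmeans2,ockra
TS1,97.3,96.6,98.5,96.6,98.8
TS2,94.5,95.4,95.5,92.5,95.7
TS3,87.4,88.3,90.1,87.1,91.2
TS4,83.9,83.6,89.9,81.9,88.2
TS5,80.8,92.3,84.3,91.2,90.2
TS6,96.1,95.6,97.0,96.0,98.2
TS7,69.4,77.0,78.0,76.8,79.2
TS8,93.8,93.5,90.0,91.4,92.4
TS9,95.3,93.2,91.0,89.8,92.7
TS10,94.0,93.7,86.9,93.3,93.7
TS11,93.4,92.7,89.5,91.3,90.9
TS12,74.6,76.5,80.1,76.0,80.3
TS13,75.8,79.9,80.1,76.7,80.5
TS14,78.0,83.8,82.4,82.2,81.9
TS15,93.8,93.0,94.1,90.6,94.5
TS16,83.2,88.3,88.1,87.1,87.9
TS17,98.1,98.2,95.7,97.8,98.0
TS18,89.1,89.3,89.5,87.0,86.9
TS19,89.4,88.2,91.4,88.0,89.6
TS20,90.5,91.5,92.7,87.3,92.2
TS21,98.4,95.7,98.0,94.9,97.9
TS22,78.3,79.6,79.3,76.7,79.2
TS23,53.0,71.0,73.8,64.4,68.9
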