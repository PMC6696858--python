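activity,met
TV watching,1.0
Eating a meal,1.3
Computer work,1.3
Reading a book on a stand,1.3
Folding the laundry,2.0
Cleaning,2.3
Walking 4.0 km/h with rest,2.7
Walking 5.6 km/h with rest,3.8
Desk work,1.3
Readying oneself for sleep,2.0
Sleeping,0.95
Lying quietly,1.0
Supine rest,1.0
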