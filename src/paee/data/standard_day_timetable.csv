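start,end,activity
09:00,09:30,TV watching
09:30,10:30,Eating a meal
10:30,11:00,Computer work
11:00,11:30,Reading a book on a stand
11:30,12:00,Folding the laundry
12:00,12:30,Cleaning
12:30,13:00,Walking 4.0 km/h with rest
13:00,13:30,Walking 5.6 km/h with rest
13:30,14:00,TV watching
14:00,15:00,Eating a meal
15:00,15:30,Computer work
15:30,16:00,TV watching
16:00,16:30,Desk work
16:30,17:00,Cleaning
17:00,17:30,Walking 4.0 km/h with rest
17:30,18:00,Walking 5.6 km/h with rest
18:00,18:30,TV watching
18:30,19:30,Eating a meal
19:30,20:00,Computer work
20:00,20:30,Reading a book on a stand
20:30,21:00,Desk work
21:00,21:30,Computer work
21:30,22:00,TV watching
22:00,22:30,Folding the laundry
22:30,23:00,Readying oneself for sleep
23:00,07:00,Sleeping
07:00,07:15,Lying quietly
07:15,08:00,Supine rest
08:00,09:00,TV watching
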