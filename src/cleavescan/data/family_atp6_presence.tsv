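sample	134	140	240	296	305	314	338	351	368	465	512	533	625	637	647	653	663
A56											+				+		
A58													+		+		+
A60		+							+		+		+		+		
A61		+							+		+		+		+		
A67	+		+		+	+		+					+			+	
A68	+															+	
A70																+	
A71	+												+		+		
A72															+		
A73											+	+	+		+		
A75									+		+	+	+			+	
A76	+		+		+	+		+					+			+	
A79											+	+	+				
A82													+		+		+
A83			+	+		+		+					+			+	
A87													+		+		+
A88	+									+			+			+	
A90							+				+	+	+	+	+		
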